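"""Per-allele MHC-I binding-affinity regressor.

Affinities (IC50, nM) are fit in a log-transformed target space,
``y = 1 - ln(ic50)/ln(50000)`` clamped to [0, 1], so that 1 nM maps to 1 and
50,000 nM (the usual non-binder ceiling) maps to 0. A small feed-forward
network (one hidden layer) regresses one-hot-encoded peptides onto y, one
model per (allele, peptide length). Models persist to disk with joblib and
reload bit-for-bit. Evaluation uses the Pearson correlation in y-space and
the ROC AUC at the conventional 500 nM binder threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .core import (
    AMINO_ACIDS,
    BindingRecord,
    Predictor,
    PredictorInfo,
    normalize_allele,
)
from . import core as _core
from .encoders import EncodingScheme, encode_set, get_scheme
from .mhc2_pssm import allele_filename

logger = logging.getLogger(__name__)

MAX_IC50 = 50000.0
BINDER_THRESHOLD_NM = 500.0
MODEL_FORMAT_VERSION = "1"
_LN_MAX = np.log(MAX_IC50)


def affinity_to_target(ic50):
    """Map IC50 (nM) to the regression target y in [0, 1]."""
    ic50 = np.asarray(ic50, dtype=float)
    if np.any(ic50 <= 0):
        raise ValueError("ic50 must be positive")
    y = 1.0 - np.log(ic50) / _LN_MAX
    return float(np.clip(y, 0.0, 1.0)) if y.ndim == 0 else np.clip(y, 0.0, 1.0)


def target_to_affinity(y):
    """Inverse transform: y in [0, 1] back to IC50 nM (50000**(1 - y))."""
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        warnings.warn("y outside [0, 1]; clamping", stacklevel=2)
        y = np.clip(y, 0.0, 1.0)
    ic50 = MAX_IC50 ** (1.0 - y)
    return float(ic50) if ic50.ndim == 0 else ic50


@dataclass
class TrainingExample:
    peptide: str
    ic50: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ic50) or self.ic50 <= 0:
            raise ValueError(f"ic50 must be finite and positive, got {self.ic50}")


@dataclass
class TrainConfig:
    """Network shape and optimizer settings (all overridable)."""

    hidden_units: int = 32
    alpha: float = 0.01  # L2 weight decay; keeps unseen-peptide output tame
    max_iter: int = 500
    learning_rate_init: float = 0.01
    batch_size: int = 64
    tol: float = 1e-6
    n_iter_no_change: int = 50
    activation: str = "relu"
    solver: str = "adam"


@dataclass
class AffinityModel:
    allele: str
    peptide_length: int
    scheme: str
    network: MLPRegressor
    train_seed: int
    version: str = MODEL_FORMAT_VERSION

    def _scheme_obj(self) -> EncodingScheme:
        return get_scheme(self.scheme)


@dataclass
class EvalReport:
    n: int
    pearson_r: float
    auc: float
    threshold_nM: float = BINDER_THRESHOLD_NM


def train_model(
    examples: list[TrainingExample],
    allele: str,
    scheme: str = "onehot",
    config: TrainConfig | None = None,
    seed: int = 0,
) -> AffinityModel:
    """Fit a per-allele affinity model; deterministic given inputs and seed."""
    config = config or TrainConfig()
    lengths = {len(e.peptide) for e in examples}
    if len(lengths) > 1:
        raise ValueError(f"mixed peptide lengths in training set: {sorted(lengths)}")
    if len(examples) < 50:
        warnings.warn(
            f"only {len(examples)} training examples for {allele}; "
            "fit may be unreliable", stacklevel=2,
        )
    allele = normalize_allele(allele)
    length = lengths.pop()
    X = encode_set([e.peptide for e in examples], get_scheme(scheme))
    y = affinity_to_target([e.ic50 for e in examples])
    net = MLPRegressor(
        hidden_layer_sizes=(config.hidden_units,),
        activation=config.activation,
        solver=config.solver,
        alpha=config.alpha,
        max_iter=config.max_iter,
        learning_rate_init=config.learning_rate_init,
        batch_size=config.batch_size,
        tol=config.tol,
        n_iter_no_change=config.n_iter_no_change,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # non-convergence within max_iter is acceptable by design
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(X, y)
    return AffinityModel(
        allele=allele, peptide_length=length, scheme=scheme, network=net,
        train_seed=seed,
    )


def predict_ic50(model: AffinityModel, peptides: list[str]) -> list[BindingRecord]:
    """Predict IC50 nM for peptides matching the model's length."""
    if not peptides:
        return []
    for p in peptides:
        if len(p) != model.peptide_length:
            raise ValueError(
                f"peptide {p!r} has length {len(p)}, model expects "
                f"{model.peptide_length}"
            )
    X = encode_set(list(peptides), model._scheme_obj())
    y = np.clip(model.network.predict(X), 0.0, 1.0)
    ic50 = target_to_affinity(y)
    return [
        BindingRecord(peptide=p, pos=1, sequence_id="", allele=model.allele,
                      score=float(s))
        for p, s in zip(peptides, ic50)
    ]


# ---------------------------------------------------------------------------
# Persistence: one artifact per (allele, peptide length)

class AbsentModelError(_core.EpitopeScanError):
    """No persisted model for the requested (allele, length) pair."""


def _model_path(store: Path, allele: str, length: int) -> Path:
    return store / f"{allele_filename(allele)}_{length}.joblib"


def save_model(model: AffinityModel, store_path: str | Path) -> Path:
    store = Path(store_path)
    store.mkdir(parents=True, exist_ok=True)
    path = _model_path(store, model.allele, model.peptide_length)
    joblib.dump(
        {"version": model.version, "allele": model.allele,
         "peptide_length": model.peptide_length, "scheme": model.scheme,
         "train_seed": model.train_seed, "network": model.network},
        path,
    )
    return path


def load_model(store_path: str | Path, allele: str, length: int) -> AffinityModel:
    allele = normalize_allele(allele)
    path = _model_path(Path(store_path), allele, length)
    if not path.exists():
        raise AbsentModelError(
            f"no saved model for allele {allele} at length {length} "
            f"under {store_path}; train one first"
        )
    payload = joblib.load(path)
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model {path} was saved with format version "
            f"{payload.get('version')!r}; this code expects "
            f"{MODEL_FORMAT_VERSION!r} — retrain"
        )
    return AffinityModel(
        allele=payload["allele"], peptide_length=payload["peptide_length"],
        scheme=payload["scheme"], network=payload["network"],
        train_seed=payload["train_seed"], version=payload["version"],
    )


# ---------------------------------------------------------------------------
# Evaluation

def evaluate_pearson(predicted_ic50, true_ic50) -> float:
    """Pearson r between predictions and truth in transformed y-space."""
    yp = affinity_to_target(predicted_ic50)
    yt = affinity_to_target(true_ic50)
    if yp.shape != yt.shape or yp.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.all(yp == yp[0]) or np.all(yt == yt[0]):
        raise ValueError("zero variance: Pearson r undefined")
    return float(np.corrcoef(yp, yt)[0, 1])


def evaluate_auc(
    predicted_ic50, true_ic50, threshold_nM: float = BINDER_THRESHOLD_NM
) -> float:
    """ROC AUC for the binder/non-binder split at *threshold_nM*.

    True IC50 < threshold labels a positive; lower predicted IC50 ranks as
    more positive. Ties in predictions are handled with midranks, so the
    result is invariant under strictly monotone transforms of the scores.
    """
    from scipy.stats import rankdata

    pred = np.asarray(predicted_ic50, dtype=float)
    true = np.asarray(true_ic50, dtype=float)
    pos = true < threshold_nM
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"both classes required at {threshold_nM} nM "
            f"(positives={n_pos}, negatives={n_neg})"
        )
    ranks = rankdata(-pred)  # higher rank = lower ic50 = more positive
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def evaluate_model(
    model: AffinityModel, examples: list[TrainingExample]
) -> EvalReport:
    records = predict_ic50(model, [e.peptide for e in examples])
    pred = [r.score for r in records]
    true = [e.ic50 for e in examples]
    return EvalReport(
        n=len(examples),
        pearson_r=evaluate_pearson(pred, true),
        auc=evaluate_auc(pred, true),
    )


def read_training_csv(path: str | Path) -> dict[str, list[TrainingExample]]:
    """Read (allele, peptide, ic50) rows; returns examples grouped by allele.

    Rows whose peptide contains a non-canonical residue are dropped with a
    logged count.
    """
    df = pd.read_csv(path)
    for col in ("allele", "peptide", "ic50"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    valid = df["peptide"].map(lambda p: set(str(p)) <= set(AMINO_ACIDS))
    dropped = int((~valid).sum())
    if dropped:
        logger.info("dropped %d rows with non-canonical residues", dropped)
    df = df[valid]
    out: dict[str, list[TrainingExample]] = {}
    for allele, grp in df.groupby("allele", sort=False):
        out[normalize_allele(str(allele))] = [
            TrainingExample(str(p), float(v))
            for p, v in zip(grp["peptide"], grp["ic50"])
        ]
    return out


# ---------------------------------------------------------------------------
# Predictor wrapper over a model store

class Mhc1MlpPredictor(Predictor):
    """Affinity predictor backed by a directory of persisted models."""

    name = "mhc1_mlp"

    def __init__(self, model_dir: str | Path, peptide_length: int = 9):
        self.model_dir = Path(model_dir)
        self._peptide_length = peptide_length
        self._models: dict[str, AffinityModel] = {}

    @property
    def peptide_length(self) -> int:
        return self._peptide_length

    def info(self) -> PredictorInfo:
        available = tuple(
            sorted({f.stem.rsplit("_", 1)[0].replace("_", "*", 1)
                    for f in self.model_dir.glob("*.joblib")})
        )
        return PredictorInfo(
            name=self.name, score_kind="affinity_nM", better="lower",
            supported_lengths=frozenset({self._peptide_length}),
            supported_alleles=available,
        )

    def _model(self, allele: str) -> AffinityModel:
        allele = normalize_allele(allele)
        if allele not in self._models:
            self._models[allele] = load_model(
                self.model_dir, allele, self._peptide_length
            )
        return self._models[allele]

    def predict_peptides(self, peptides, allele) -> list[BindingRecord]:
        return predict_ic50(self._model(allele), list(peptides))


_core.register_predictor("mhc1_mlp", Mhc1MlpPredictor)
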