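query,protein,start,hits
PSGTWLTYTGAIKLD,N,326,GTWLTYTGAIKLDDK
SFIEDLLFNKVTLAD,S,816,FIEDLLFNKVTLADA;DLLFNKVTLADAGFI
YEQYIKWPWYIWLGF,S,1206,
VLKKLKKSLNVAKSE,nsp8,3976,VVLKKLKKSLNVAKS;EVVLKKLKKSLNVAK
KLLKSIAATRGATVV,nsp12,4966,RQFHQKLLKSIAATR
EFYAYLRKHFSMMIL,nsp12,5136,NEFYAYLRKHFSMMI;YLRKHFSMMILSDDA
LMIERFVSLAIDAYP,nsp12,5246,
TSHKLVLSVNPYVCN,nsp13,5361,
NVNRFNVAITRAKVG,nsp13,5881,VNRFNVAITRAKVGI
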