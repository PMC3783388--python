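>LINA_RT
IMICVGIPDHPPEGPPMQVR
>LINA_RH
WYACEDRYTHSRTFFNTDIQ
>LINA_YR
MLEDEGMYEQQVWICNMMKL
>LINB_RT
YNMEVWKCGIQCNLYFIYYG
>LINB_RH
GEWTSNFCFFNVYGSEGADG
>LINB_YR
TPQLICTYMWRNTNSEAQIS
>CLADE1_RT
PQASMVNRGPSSAPYPDQES
>CLADE1_RH
TLFGSLHAGWRSHEFKFICL
>CLADE1_YR
GYHDFTQDEHMFDLSHDGAP
>CLADE2_RT
GEVRAVWFLKQQRYQETSMS
>CLADE2_RH
ATYSYSFRALIGHKPVESAL
>CLADE2_YR
KEEECWVIVSGMMQWFVQLM
>CLADE3_RT
WLLNEHTEACSGLIEDYAQH
>CLADE3_RH
THPRDRGWFWVGLGIMYKPL
>CLADE3_YR
AHEFCGEPIPYFTEMLPHFT
>CLADE4_RT
IVLAFYLHGSTPNNPDPYNV
>CLADE4_RH
KMCPIKECWVCGSNVVNTCF
>CLADE4_YR
VQLCWDGHVVFTMLHHVKTN
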