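>GEN_RT
VYWEFKTHSNEVECWVNKVLSEFIIFQVWMLAITEGGAVTDSWEMMPQTQDWVQWKHESQASKCYLYYFFLSWHQIIYTGGGVANACHEFHGHLSTLPIMNVHSAKRRHIEITHALIEPL
>GEN_RH
GPSNVKCNCPMCEMAQAEGHKITCVVQASFIYGFDLDRSCVQVIRSQNQSYLAEFHGYCWTFKTNYPCGNLVARFVSGSF
>GEN_YR
WIWCRFNFMCRPNWNSLDALKVKTYDTAWWVDAVKETHRHGNSMQLQVFYYHPVFGQGIWTVQNTLNETKDQSHNSTANNMQASSQAEPNMNFFSCVKKM
>GEN_MT
PIGSAEAVQMTNKLLDHGVTKATMHRQDKRRSPFDAKNQQNKAECCGPFATSINWRPNVVHPKLSMYYFSTTYNISPCPYADHACSFCIS
>DIRS_RT
VREEHKTHNLEDECWVNKVLSVFIIFAMVFLAVTEGGAVTDSWEMMPQTQSDVRWCGESQASKCYLYYFFLAWHAYIYTGGCVANHCHEEHGHLLHLPEDAVHNSKRRFDEITPWLIQGL
>NGARO_RT
AYWEFKWMSAEMQCWVNKVLSEFIISQVWWLVITFTCAVTDSWEMMAVTQDWTFDKHESQASKCYGTYPFLHWYTIIETGGLVANAEHEFTGHLSFLPISNKHSGKRRHIEFANKYIEPL
>DIRS_RH
PPPNVVCNCPFGLSAQAEGHIDTFVWQKSNFYIFDLDRSCVQVIRSQVQSYLAYFHGYCPTEKTNYPCGNTHARTYSGSL
>NGARO_RH
GPSNVKCNRPICEMAQAEHHWITMVVYASNHYMFDHQRSGHQVARSQNVSYLAEFHSIDWGFKTNYPHGKLPAQFVCGSF
>DIRS_YR
WHWCRFRFMCRPNQQSLEANKVKTYDTNWWVMAVKETYRLGNSMQIQVPYYHPVFGGTHYRVTNTLNENNDQIHNSTAMFMWASSQAAPLMNSFSCWKAA
>NGARO_YR
WIWVRFNFMCRDNWNMPDAWQVFHYDWWWWVDATKETWRHGQSYQLQVFRRRPVFSQRIWTVQNTLNELGAQYIHSTDNNMQATSQANPNRLFFSCVKKM
>DIRSA_RT
VREEHKTHNLEDECWVNKVLSVFIIFAMVFLAVTEGGAVTIMICVGIPDHPPEGPPMQVRASKCYLYYFFLAWHAYIYTGGCVANHCHEEHGHLLHLPEDAVHNSKRRFDEITPWLIQGL
>DIRSA_RH
PPPNVVCNCPFGLSAQAEGHIDTFVWQKSNFYIFDLDRSCWYACEDRYTHSRTFFNTDIQTEKTNYPCGNTHARTYSGSL
>DIRSA_YR
WHWCRFRFMCRPNQQSLEANKVKTYDTNWWVMAVKETYRLMLEDEGMYEQQVWICNMMKLRVTNTLNENNDQIHNSTAMFMWASSQAAPLMNSFSCWKAA
>DIRSB_RT
VREEHKTHNLEDECWVNKVLSVFIIFAMVFLAVTEGGAVTYNMEVWKCGIQCNLYFIYYGASKCYLYYFFLAWHAYIYTGGCVANHCHEEHGHLLHLPEDAVHNSKRRFDEITPWLIQGL
>DIRSB_RH
PPPNVVCNCPFGLSAQAEGHIDTFVWQKSNFYIFDLDRSCGEWTSNFCFFNVYGSEGADGTEKTNYPCGNTHARTYSGSL
>DIRSB_YR
WHWCRFRFMCRPNQQSLEANKVKTYDTNWWVMAVKETYRLTPQLICTYMWRNTNSEAQISRVTNTLNENNDQIHNSTAMFMWASSQAAPLMNSFSCWKAA
>NGARO1_RT
AYWEFKWMSAEMQCWVNKVLSEFIISQVWWLVITFTCAVTPQASMVNRGPSSAPYPDQESASKCYGTYPFLHWYTIIETGGLVANAEHEFTGHLSFLPISNKHSGKRRHIEFANKYIEPL
>NGARO1_RH
GPSNVKCNRPICEMAQAEHHWITMVVYASNHYMFDHQRSGTLFGSLHAGWRSHEFKFICLGFKTNYPHGKLPAQFVCGSF
>NGARO1_YR
WIWVRFNFMCRDNWNMPDAWQVFHYDWWWWVDATKETWRHGYHDFTQDEHMFDLSHDGAPTVQNTLNELGAQYIHSTDNNMQATSQANPNRLFFSCVKKM
>NGARO2_RT
AYWEFKWMSAEMQCWVNKVLSEFIISQVWWLVITFTCAVTGEVRAVWFLKQQRYQETSMSASKCYGTYPFLHWYTIIETGGLVANAEHEFTGHLSFLPISNKHSGKRRHIEFANKYIEPL
>NGARO2_RH
GPSNVKCNRPICEMAQAEHHWITMVVYASNHYMFDHQRSGATYSYSFRALIGHKPVESALGFKTNYPHGKLPAQFVCGSF
>NGARO2_YR
WIWVRFNFMCRDNWNMPDAWQVFHYDWWWWVDATKETWRHKEEECWVIVSGMMQWFVQLMTVQNTLNELGAQYIHSTDNNMQATSQANPNRLFFSCVKKM
>NGARO3_RT
AYWEFKWMSAEMQCWVNKVLSEFIISQVWWLVITFTCAVTWLLNEHTEACSGLIEDYAQHASKCYGTYPFLHWYTIIETGGLVANAEHEFTGHLSFLPISNKHSGKRRHIEFANKYIEPL
>NGARO3_RH
GPSNVKCNRPICEMAQAEHHWITMVVYASNHYMFDHQRSGTHPRDRGWFWVGLGIMYKPLGFKTNYPHGKLPAQFVCGSF
>NGARO3_YR
WIWVRFNFMCRDNWNMPDAWQVFHYDWWWWVDATKETWRHAHEFCGEPIPYFTEMLPHFTTVQNTLNELGAQYIHSTDNNMQATSQANPNRLFFSCVKKM
>NGARO4_RT
AYWEFKWMSAEMQCWVNKVLSEFIISQVWWLVITFTCAVTIVLAFYLHGSTPNNPDPYNVASKCYGTYPFLHWYTIIETGGLVANAEHEFTGHLSFLPISNKHSGKRRHIEFANKYIEPL
>NGARO4_RH
GPSNVKCNRPICEMAQAEHHWITMVVYASNHYMFDHQRSGKMCPIKECWVCGSNVVNTCFGFKTNYPHGKLPAQFVCGSF
>NGARO4_YR
WIWVRFNFMCRDNWNMPDAWQVFHYDWWWWVDATKETWRHVQLCWDGHVVFTMLHHVKTNTVQNTLNELGAQYIHSTDNNMQATSQANPNRLFFSCVKKM
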