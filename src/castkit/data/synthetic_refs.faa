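>Cas12k|synthetic-1
MYWLAWYCRQFYTWSRRTLFKYPWIYHIYWRTAYYNIQDWKAHHSQMWECMAFHLMGRNWIDRETMGFCK
NLEYFETRLWHYKVMDMMEQDECQRPDTKAVISQLTNDKNKESVTSQSWILKNVQDIIMIWHEMGSHMVE
LQTAWFPRIKAQWHSMGKTYGVDNATSNIVCQKADMAVSQAVQEEYGAASSAMNIFFNCARFFDCACYYC
AEVISACRECEEEFGSTLSVISGGTSYMYFDFEMRYKIQHEAYVHDQWMVIYVNLACGMDPTCNNAILDE
EVFFTMHYNHILEEHPQNNMMYLRVGHYQHCHCRCFAQFVQSDYHKASRASGNRNTNVHLPRQGAAAAIF
SYCMIGGVVPREKIIFKPEFKSWFASFDAWCAIQNLCNMPGCGDQLCMVSPVDLETPILFDWENREVYPK
GLMVRNSGMDLQKKHLPNRLISCMCNRLHFPPHTAPLSNFNFSFEVQWGSRSLCFRAQWACSNHVYLRWN
ICVWSYQCWCIFQGDWVKVIHKNWWYGINSYSLIPRHPNGLRTSSAILFIYCPSKFMRQREPYIAWRKDD
HSFGPAYKLHEFWYQKEYNPFMGACTGMSCILDYLGYDDFMNFDSLIAILMPEFREFTRFIVACGPIAVD
NICSMTQLY
>Cas12k|synthetic-2
MYWLAWYSRQFYTWSRRTLFKYPWIYHIYWRTAYYNIQDWKAHHSQTWECMAFHLYGRNWISRETMGFCK
NVEYFETRGPHYKVMDHMEQDECLRDDTQAGISQLTGDKNKEIVTSQSWILKNYQDIIMIWLEMGSCMVE
LQVNWYPFIKAQQHKMGKEYGVDNATSVWVCQKPDMAVSQAVQEEYGAMSSAMNIFVNCFRFFRCACYTC
AEVISACMECEIEFGSSLSVYSGGHSYMYADTEMAYKIQHEPYVHDQEMVIYVNLACGMWPTCNNAALDE
SVFCSMHYNHILEEHPQNNMMYLRVGHEQHCHCRCFRQFVQSCYHKADRASGNRNTQVRLPRQGAAAAIF
SYCMIGGVVPREKIIFSPEFKSWNASFDAWCAIQYLCNMPGQGDQLCMVSPVDVETPILFDWENREVYPE
GLNTQNSGMDLQQKHLPNSLASCMCNRLHKPPHTAPGSNFNFSFEVQFGSRQLCFRAQCACSNHVYKRWW
ICVWKYQCWHIFQGDWVKVIHKNWRYGINSYLSIPRNPNGLRTSSALLFIYCPSKFMRQREPRIAFRKDD
ISFGPWYKLWEFWYQKEYTPFIGACTGMDCILDSLIYDPFMNFDSPIAIQMPEQREFTRFWVCCGPIAVD
NICVMTQLY
>TnsB|synthetic-1
MKPWLFLFIAACASEWKAPMFAFAGMETCWYLGIITQARYSYAQDKSCTNTGLQGFSWMEQRVWNLALEN
QLAAYTGEVEDEAQHMFPCQQEQAYGEESEWEMMLIECGCEDGSISWMDVVTHKMQIAFMCDNSEVSWPQ
VKVFEQVRLIGKNIHHVRVREVYCGLQWKIMTHNWEQWQSSREGATVHWWDGFRMDTEYECILPYRSVPS
YWKFDVIMHAWMGMNAITMFLDFGWERVKIMQPFNGTQNSNLKRGEQPMQCRAGGAASHMVAENCCMFFY
DEVHWCAIYVMFPKADKEWTNQYNCNDQVIRLRTKDVPCPNTCQYEVCIGGPPHLRIWEAVTTLKWTICQ
DWNFVPYYQFYIGRPLHSYIWDKVFGERSGPETKCGWVSHADDVIWPWSSGKNRFVCCDHAQNWPMEYWI
SQALCQECSPFDAYQLGDPIVCQDPNKRLFYAESCRNDHIFRCGHDWMYFPPFKKQPHDMSYQVGKVAPN
DQPVGRICWCKHLRKMMTDCKGPRYFYYAWGHLRIYRSMSNFCRYWVSICGNEIIHENIEFTQGSEDKSE
>TnsB|synthetic-2
MKPWLFLFIAKCASQWKAPAYAFAGMETCWPAHIQTQARYSYGQDKSCTNTGLQGFSWMTQREWNLALLN
VLAAYTIEVEDLAQHMSSCQQEQAYGEESEWEMMLCECGCEDTSISWMDVATHKMQIAFEHDNSEVSIPH
SNVFEQVRLIGKRKHHERAREVYCGLQTKIMTHNWESWQVSREGATVHHWDGFRMDTHYEYELPYRSVPS
YWKFMVIMHAWMGMNIITMFLDFAWELVKIMQPSNGLQNSNLKRHEQYMQCRAGGAAMHMPQENCCMFFY
DEVHWCAIYVMFPKADKMTTNQYNCNDQVIRLRHKDVPLPNTCQYEVCIGGPPHLRAWEAVTTLKWTICR
DWNEVPYYQFYFGRPLHSYIWIKVFGERSGPETKCGTVSHADDVIWPWSSIKNRFVCCDHAQNWPMQYWI
SNALCQECSPFDAYQLGDPIVCQCPNKRVFIIESCMNDHIFRCGHDTMYFPPCFKQPHDMMYQVGQVAPN
DQPQGCNCWCKCLRKMRTDCKGPRYFYRAWGHLRIYRSMSNFCQYWNSICGNCIIHEFIEFTQGMEDMDE
>TnsC|synthetic-1
MTAHVNKFLKQWECNKTLPGFWQRQWITIQFDWKEPHAQCNRRGWWLKHMLVEPISYIIDPQWWDMKHWW
YLKTSCQFTEGNWNDFIIMSASGNECTGGQKKWADILEGYVKLHKESGWGQYIPAFHYWQQDVAKNLRKQ
ELWANRRAHPQEHFKPESTKHKTMSAVETTAVNDYCTAEFTEGIFGYFVTQYTSQIFGIQRDAGAFLGFV
SRGLYFNSMLKQDGCNVWFNWWTALTQAPDFGFVDMSNMGHVNQDHQNCTETKWKLVKWGKDGKMDQTRC
QEGYHIMPNKQWGGLFDQNMVYSAIVAIFNRFYSLGFCVHIHHMMWNPKGHKPECKRACNWGKKNCHHEG
VQGYNAHGNMRGQLIDLHCVYFYMMNIYLDGYFQVKYRHHHLFGIVSVQHLCQDRGQQSKHQIFYKWWIA
SLILKRHYMT
>TnsC|synthetic-2
HTAHVNKFLKQWEDNKKLRGFAQRQWITIQFDWKAPHAQCFRRGWLNKGMWVELISYIINPQWWDMKHWW
YLKTSCQQTEGNWWDEIIMSASGNECTDGQKKWADILEGYVKKHKNSGWGIYIPAFIYWWQDAAENLRKQ
ELWACRRAHPQCHFKPESTKHKTMSQTETTAVNDSCTAEFTEGIFVYFVTRYTSQIFGIARKAGFFLGFY
SRGLYFNSMLKQDGCNLWFNWATALTQACDFGFVDMLNMGHVNWDHQTCTSYKWKLDKWGKDGKMDQTGC
MEGYEIHPNKQWGGLFDQNMVYSEIVAYFRRFYSLGFCVHIHQMMWNPKGHRPEPIRLCNWGKKNCHHEG
VQGYNAHGNMRGQLIDLHCVYFYNMNIYLDGYFQVKYRHHHLFGIVSVMHLCHDRGQNSKWIIFYIWWIA
SLILKRHFMT
>TniQ|synthetic-1
MLRLSNAVPMAIQMADSVKSAPQTILGDFCKASTMRNHPMPPIDVPDKMSKTRDEVPTSTAMRARLHYYC
DWPVLSTADTFHLPYRPDFMFHWNVWHETFYSDSNDNVSLIDNKYYRHKAAGMWKQLESVSTADPLYWMT
QACFQQMIIEEPCPNMGECPVYFSGNNFSNTPLDQMDIYPPPPREVDWCMWRMSLAHEGKQITKKGYYRD
RCQPGIKARG
>TniQ|synthetic-2
MLRLSNAVPMAIQMADSGKSAPQTILSNFCKMSTMRNEPMPAIDVVDKMSDTRDEEPTSPWMRPRLHYYC
DWPKPATADYFHLRYRPDFMFHWNVEHETFYADSNDNVSLIDNKYYRHKAAGMNKQLESASTAEPLMWMT
SACFQQMIIEEPCPNMGECDVYFSGNNFKNTPLDQQDIYPPPPWEEDWCMWRMSLASEGKQITWKGYYRD
RCQPHIKERG
>CvkR|synthetic-1
MMFKLRVMNYFKTTAPFHMDRAQIPEQQEHQNESPECPMVKDSEETMTQRARGHGLCYMAQYHIIHEEQA
RVTHHMMVAQRITQRQRQYWSTTAQQIAMGDYDGQSDEFPTHMISRAYPIIGNIHHFLTTWVRQPDDLLT
LVCSWSSVLKMIWPSNFMVWVVAMHCMELEPPRCLAKNDAHDNEN
>CvkR|synthetic-2
SMFKLRVENYFKTTAPFEKDRAQIWPQQEHQNEQPECDMAKDGEETMTQFARGHMLCYMAMYEIIHEECA
RVTHHCMVATRITQRQRQYWSTHQQQIAMGDYDGQSDEFPTHMISRARPIIGNIHHFLYWWVRQLDDLLY
LVCSWSLVLDMIWPSNFMVWVVAQHCMELEDPRCLAKNDAHDNEN
>CvkR|synthetic-3
MMFKLRVMMYFKTEAPFHMDRAQITEQQEHCNERPECPMVKDLEEISTQRARGHYLSYMAQYFIIDKSQA
RVTHKMMVAQRITQRQRDFYSTTAQQIAMGDYDGQSDFFPTHMISRAYPIIGGIHHFLTTWVTQPDDLLT
LVCSWSSVLKMCWPSNFGVWVVAMHCMQLEPPRCLNKNQAHHEEN
>Arc_1|synthetic-1
MFRPLEVQEYSSYICLSNSFVNYYVHKKMVFSMSLNKVQMRTAHANTIDPIFWTEFYMWMKLFAYQYMQW
SV
>Arc_1|synthetic-2
MFRPLVVQENSSYICFSNSFVNYCVHKKMVFSMSLNKVQMRVAHANTSDPIFWTEFYGCMNLFCYQDMQW
SV
>Arc_1|synthetic-3
MFRPLIVVEYAIYICLSNSFVNYYVHKQLVFRMSLNKVQTRTAHANTIDPIFNTEMYMWMKLEAYQYMQW
SV
>Arc_2|synthetic-1
MQHLMQMMRMPFCPNNNCWQIAWYEWYGMDIRMENDFCIHIPNLLAELAFDSNYEIYMMKETDYFFNMGK
>Arc_2|synthetic-2
MHHLMQMMRMPFCPNENCWQIIWYEWYGPDIRSEHDFCIHIHNKYAELAFDSNYEIEMMKETDYFFNMGK
>Arc_2|synthetic-3
MQTTMQMMRCPFCPNVNIWQIAWYEWYGRDIRMENDFCIHIPNLLAELAFDSEYQIYMMKETDDFFNNGK
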