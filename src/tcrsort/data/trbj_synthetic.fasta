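>TRBJ1-1 anchor_fw_end=12
GTGATCTCGTTCGGGCCAGGCATGCGTTACAGAAAAATTCTTGTC
>TRBJ1-2 anchor_fw_end=15
CAAATCCAGCTGTTCGGGGCAGGAGTACCAACTCCGATACTGTAT
>TRBJ1-3 anchor_fw_end=18
TCATTATCACGTCCGTTCGGTTTGGGGCATCTTCGGGTGAGCCAC
>TRBJ1-4 anchor_fw_end=12
TACAGATTGTTCGGGAGAGGGTCCGATACGGTGCATAATCCATCC
>TRBJ1-5 anchor_fw_end=15
AGGATGACGAGGTTCGGCATAGGACGCAGCACCCAGTCCAAACCA
>TRBJ1-6 anchor_fw_end=18
GACTATCAGGATAGCTTCGGCGCGGGTCTACGGGCCTCACTGTCG
>TRBJ2-1 anchor_fw_end=12
AGCGTGAGATTCGGGGAAGGGAATCTTAACCCTCTCCCAAAACCG
>TRBJ2-2 anchor_fw_end=15
TACATCGACGCTTTCGGATCCGGGCGGCTCGAGTCCGCTATCTCA
>TRBJ2-3 anchor_fw_end=18
CAGTCAATACAAAGTTTCGGCAGCGGACGCAGTACCTCTTCAACC
>TRBJ2-4 anchor_fw_end=12
CCGGCGTCCTTCGGGCGTGGTCACAACATAGTCCGAGTGGAATTG
>TRBJ2-5 anchor_fw_end=15
CCTACAAAAGTGTTCGGGTTAGGTAATGACCGTGTTGCTGATCTT
>TRBJ2-6 anchor_fw_end=18
TACGTAATCCCGCAATTCGGTCAAGGAGAGCAGGCAACACCCTTG
>TRBJ2-7 anchor_fw_end=15
CTCCAAACACCGTGGGGGCGCGGACTAGAATCCCCGGTGATTCAC
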