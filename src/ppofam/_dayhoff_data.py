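"""Vendored Dayhoff (1978) amino-acid substitution model constants.

``DAYHOFF_EXCHANGEABILITIES`` is the lower triangle (row-major, rows 2..20)
of the symmetric exchangeability matrix and ``DAYHOFF_FREQUENCIES`` the
equilibrium amino-acid frequencies, both in the classic PAML amino-acid
order ARNDCQEGHILKMFPSTWYV. These are the published empirical values that
define the Dayhoff/PAM model; see :mod:`ppofam.pam` for how they are turned
into a 1-PAM transition matrix.
"""

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

DAYHOFF_EXCHANGEABILITIES = [
    27, 98, 120, 36, 89, 198, 240, 23, 65, 41,
    26, 72, 18, 250, 409, 371, 0, 24, 208, 32,
    0, 23, 246, 1, 9, 240, 64, 15, 464, 90,
    14, 103, 154, 26, 201, 8, 24, 905, 0, 103,
    148, 139, 535, 77, 34, 318, 1, 14, 42, 495,
    229, 23, 95, 15, 0, 134, 1153, 125, 86, 24,
    0, 71, 0, 0, 13, 95, 66, 0, 0, 18,
    0, 0, 11, 28, 44, 0, 0, 0, 0, 19,
    161, 16, 0, 96, 49, 716, 28, 606, 18, 73,
    153, 114, 0, 153, 56, 53, 0, 0, 35, 81,
    43, 61, 11, 83, 30, 0, 51, 79, 34, 0,
    22, 37, 10, 0, 7, 27, 17, 15, 34, 234,
    30, 0, 0, 54, 7, 44, 26, 0, 48, 94,
    35, 22, 27, 127, 44, 257, 46, 336, 196, 12,
    24, 192, 0, 37, 889, 18, 527, 157, 32, 17,
    33, 46, 28, 175, 243, 0, 33, 96, 136, 0,
    13, 10, 92, 17, 62, 104, 0, 0, 258, 11,
    46, 13, 76, 698, 12, 245, 78, 0, 0, 48,
    550, 75, 34, 30, 0, 42, 157, 61, 0, 28,
]

DAYHOFF_FREQUENCIES = [
    0.0871269129, 0.0409039591, 0.0404319596, 0.0468719531,
    0.0334739665, 0.0382549617, 0.0495299505, 0.0886119114,
    0.0336179664, 0.0368859631, 0.0853569146, 0.0804819195,
    0.0147529852, 0.0397719602, 0.0506799493, 0.0695769304,
    0.0585419415, 0.0104939895, 0.0299159701, 0.0647179353,
]
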