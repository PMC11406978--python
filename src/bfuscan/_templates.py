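"""Fixed subunit template protein sequences for the synthetic generator.

One template per subunit role.  The BfuA template carries exact instances
of the three H-cluster binding motifs at known positions (P1 at residue 61,
P2 at 151, P3 at 261, 1-based); the wildcard fifth position of the P1
instance holds the Ser typical of most sub-types and is switched to Cys
for sub-type IV variants.  All templates are free of spurious motif
matches, and the generator masks the motif windows when applying
divergence so planted BfuA proteins always scan cleanly.
"""

# 0-based template coordinates of the motif instances in TEMPLATE_A
P1_START, P2_START, P3_START = 60, 150, 260
P3_END = P3_START + 15          # past-the-end of the last motif
P1_POS5 = P1_START + 4          # the sub-type discriminating wildcard position

TEMPLATE_A = (
    "MAYCTLWIFWVSHNHFKTRLSGKFVIDKSMHWADYWQRFVQCAWVAKLFAYYCFWCKHDFATSCSPVWAE"
    "NWWINSHLWHRQFTRSFTWWDNMWSDYPNQICDWGCHGGEKWLDGKFNCLRWTEIWWTITILFSKKAAAR"
    "NQQEACGNITVLMPCTAKKIKVDPDWKFRHRCAVHWMHCYRYSMYQDRMKTTMGEAEMSSKDGQKGKELC"
    "MHVKFPIIFHDDEKPAVNYHVPDVEMMPTGFCTKDWDRACFKFYVEHSLWERMTCPGGCVNGAGQECWMG"
    "LPTLMPAGLSAFRIQWGYREFRAEEGPVQKIHMFGCNIIYDEFSVWSYHYCWFIDFPMKEISETTWGAER"
    "SEQCIPHDFDNHIIWRLKKPRPFHNEHTIMEPNMTTKNHMQGRELWVETAFSYFVGWIGEETDSYFSKAW"
    "NQYTYPEASENHYHDMFHYLQIFIRQPGET"
)

TEMPLATE_B = (
    "NSHTDMLSQMSHGLFKKINMYVHRDRWDKYCPAWGRLPGSIWFQIFSPPDRVDNNHNGRPADGWIEHPIQ"
    "GNWRPQWAHMRGPYYSAETMMDTYQGHWECWDGNDIIPQTNFWVKHAPGWWPTYYYINQMRHTVTCYHRP"
    "LPKQRWKHPLPNPSANTDDNWKFKECHWVRITHEVQICTSKEYVNNMQMTPEMSKRWKKINLVMGQCSKT"
    "HNCMDNAWWWQLRRPCMCNYRKMCYWWYITGIPEQHIDIVRATDWCEMRYFAKSKPFRRRCEYDGFIVEG"
    "TVAEEQGALLSPENRYSKTDFSTLHSGSVLLNPQGSPCEFNYAQACHQIAPWFTWCGIKARWYYHDCCYA"
    "CKSRHDFPATFIPWMVDWVIWMAFPYLNRYECMIKCLSNAVDQGSSVTDIQLRQVSWRVHKTVANESDVK"
)

TEMPLATE_C = (
    "KNIGFTNRLDLVQPAHGYEVTTMISPTSSHIHYFAVPPTSYPCQVVWREWYWAIYSCPEESNLVKIQVAW"
    "FSANKNGQSCIWYPWKFPTTCHEETYREWRLKMPKPQGYLWEVPWGLFIKLVHVNRSDNNFGRWTLILTM"
    "WDTLPYAYDLEAGMGYIMAL"
)

TEMPLATE_D = (
    "EWHIIWTGCPPYMHMPEAGGWVWRLIVYQSEAVYPHMGWAWETSTTECVRNQCHVELVYVNRGDWKGLAP"
    "MASFYDDKRPGLVAYAMQAPTSWLPFKVATFMYHKPAEFRNYNIQCLGMH"
)

TEMPLATE_T = (
    "TGNNPIHFRRMPQAHNIEFLQAWPEWWGQPRIVPDMGLFLYHYQLIRPPWNSLGWDTYGPKNMYVCSYPL"
    "AASTPVVHMSFTGWAFDQPHEPMELSHQFNLSMFMIWHPERAYYYVHFKSWYLDVEEAHEDWYFPRSDYI"
    "NGWHVQKIIIDLTFNCMENAWNYSWVRKMSRDIPWEGPYKALEPCSMQMCHTTNMASEPLFWGWVACAYK"
    "NHRHCNKNKYWLDVWQGYMANCWEGMKREITKGDVHYCTAYCEDVLAVREGYKKVGTKYMEQGWMAVWPA"
)

TEMPLATES = {
    "A": TEMPLATE_A,
    "B": TEMPLATE_B,
    "C": TEMPLATE_C,
    "D": TEMPLATE_D,
    "T": TEMPLATE_T,
}
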