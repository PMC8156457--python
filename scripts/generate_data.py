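"""One-off generator for the packaged synthetic data files.

Produces:
  src/cfmito/data/chrM_synthetic.fa        16,569-bp synthetic circular reference
  src/cfmito/data/haplogroup_tree_synthetic.tsv  ~50-node reduced haplogroup tree
  src/cfmito/data/clinvar_synthetic.tsv    ClinVar-style annotation stand-in
  src/cfmito/data/ancestral_variants.tsv   ancestral variant list

Deterministic (fixed seed). Run from repo root: python scripts/generate_data.py
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "src" / "cfmito" / "data"
DATA.mkdir(parents=True, exist_ok=True)

L = 16_569
BASES = np.array(list("ACGT"))
# human mtDNA-like base composition (A/C-rich heavy strand)
COMP = np.array([0.309, 0.313, 0.131, 0.247])

rng = np.random.default_rng(20210514)


def gen_reference() -> str:
    seq = rng.choice(BASES, size=L, p=COMP)
    # salt in a few longer homopolymer stretches reminiscent of the HV2/HV1
    # C-stretches so run-length >= 5 territory is well represented
    for start, base, n in [(303, "C", 7), (311, "C", 6), (16184, "C", 5),
                           (568, "C", 6), (5895, "C", 6), (8270, "C", 5),
                           (956, "C", 5), (12418, "A", 5), (3566, "C", 6)]:
        seq[start - 1 : start - 1 + n] = base
    return "".join(seq)


seq = gen_reference()
with open(DATA / "chrM_synthetic.fa", "w") as fh:
    fh.write(">chrM synthetic mitochondrial reference (16569 bp, circular)\n")
    for i in range(0, L, 70):
        fh.write(seq[i : i + 70] + "\n")
print("reference written:", len(seq), "bp")

# ---------------------------------------------------------------- tree
# Superclades and a couple of nested levels; names are PhyloTree-style.
TOPOLOGY = {
    "H": ["H1", "H2", "H5"],
    "U": ["U2", "U4", "U5"],
    "J": ["J1", "J2"],
    "T": ["T1", "T2"],
    "K": ["K1"],
    "C": ["C4", "C5"],
    "D": ["D4", "D5"],
    "M": ["M7", "M8"],
    "N": ["N1"],
    "W": ["W1"],
    "B": ["B4"],
    "I": ["I1"],
}
GRANDCHILDREN = {
    "H1": ["H1c"], "H2": ["H2a"], "U5": ["U5a", "U5b"], "J1": ["J1c"],
    "T2": ["T2b"], "C4": ["C4a"], "D4": ["D4a", "D4b"], "M8": ["M8a"],
    "K1": ["K1a"],
}
GREATGRAND = {"H1c": ["H1c4"], "H2a": ["H2a1"], "J1c": ["J1c2"], "D4a": ["D4a1"]}

nodes = [("mt-MRCA", "", [])]
used_pos: set[int] = set()

# variant positions concentrate in the mutational hot spots (3-5, 11-13 and
# 15-16 kb; the last range includes the control region)
HOTSPOTS = [(2001, 5000), (10001, 13000), (14001, 16569)]


def draw_pos() -> int:
    if rng.random() < 0.315:
        lo, hi = HOTSPOTS[rng.integers(len(HOTSPOTS))]
        return int(rng.integers(lo, hi + 1))
    return int(rng.integers(1, L + 1))


def draw_variants(n: int) -> list[str]:
    toks = []
    while len(toks) < n:
        pos = draw_pos()
        if pos in used_pos:
            continue
        used_pos.add(pos)
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        toks.append(f"{pos}{alt}")
    return toks


for clade, children in TOPOLOGY.items():
    nodes.append((clade, "mt-MRCA", draw_variants(int(rng.integers(14, 19)))))
    for child in children:
        nodes.append((child, clade, draw_variants(int(rng.integers(14, 19)))))
for parent, children in GRANDCHILDREN.items():
    for child in children:
        nodes.append((child, parent, draw_variants(int(rng.integers(14, 19)))))
for parent, children in GREATGRAND.items():
    for child in children:
        nodes.append((child, parent, draw_variants(int(rng.integers(14, 19)))))

with open(DATA / "haplogroup_tree_synthetic.tsv", "w") as fh:
    fh.write("# synthetic reduced mitochondrial haplogroup tree: name, parent, defining variants (POS+ALT)\n")
    fh.write("name\tparent\tvariants\n")
    for name, parent, toks in nodes:
        fh.write(f"{name}\t{parent}\t{','.join(toks)}\n")
print("tree written:", len(nodes), "nodes")

# ---------------------------------------------------------------- clinvar
# Significance vocabulary is closed; diagnoses separated by '|'.
CLINVAR_ROWS = [
    # hgvs-style key fields: pos, ref, alt, type
    (15301, "G", "A", "SNV", "rs193302991", "140591",
     "Conflicting interpretations of pathogenicity", "Familial cancer of breast"),
    (14783, "T", "C", "SNV", "rs193302982", "140588",
     "Conflicting interpretations of pathogenicity", "Familial cancer of breast"),
    (15452, "C", "A", "SNV", "rs193302994", "143925", "Benign",
     "Neoplasm of ovary|Leigh syndrome"),
    (3010, "G", "A", "SNV", "rs3928306", "441149", "Drug response", "Not provided"),
    (13708, "G", "A", "SNV", "rs28359178", "9696", "Benign",
     "Leber's optic atrophy|Leigh syndrome"),
    (489, "T", "C", "SNV", "rs28625645", "434926", "Benign", "Leigh syndrome"),
    (10400, "C", "T", "SNV", "rs28358278", "434744", "Benign",
     "Leigh syndrome|Familial cancer of breast"),
    (961, "T", "G", "SNV", "rs3888511", "9627", "Pathogenic",
     "Nonsyndromic sensorineural mitochondrial deafness"),
    (15511, "T", "C", "SNV", "rs193302997", "143928", "Pathogenic", "Neoplasm of ovary"),
    (951, "G", "A", "SNV", "rs199474663", "434925", "Pathogenic", "Not provided"),
    (980, "T", "C", "SNV", "rs199474664", "434927", "Pathogenic", "Not provided"),
    (1008, "A", "G", "SNV", "rs199474665", "434928", "Pathogenic", "Not provided"),
    (8410, "C", "T", "SNV", "rs199474666", "434929", "Pathogenic", "Not provided"),
    (11560, "A", "G", "SNV", "rs199474667", "434930", "Pathogenic", "Not provided"),
    (14470, "T", "A", "SNV", "rs199474668", "434931", "Pathogenic", "Not provided"),
    (15262, "T", "C", "SNV", "rs199474669", "434932", "Pathogenic", "Not provided"),
    (15514, "T", "C", "SNV", "rs199474670", "434933", "Pathogenic", "Not provided"),
    (15833, "C", "T", "SNV", "rs199474671", "434934", "Pathogenic", "Not provided"),
    (9906, "G", "", "del", "rs869183622", "440701", "Likely benign", "Not provided"),
    (10151, "A", "", "del", "rs869183623", "440702", "Likely benign", "Not provided"),
    (9916, "C", "", "del", "rs869183624", "440703", "Likely benign", "Not provided"),
    (2193, "T", "", "del", "rs869183625", "440704", "Likely benign", "Not provided"),
    (9808, "", "T", "ins", "rs869183626", "440705", "Likely benign", "Not provided"),
    (750, "A", "G", "SNV", "rs2853518", "441147", "Benign", "Not provided"),
    (2706, "A", "G", "SNV", "rs2854128", "441148", "Benign", "Not provided"),
    (263, "A", "G", "SNV", "rs2853515", "441146", "Benign", "Not provided"),
    (15326, "A", "G", "SNV", "rs2853508", "9944", "Benign",
     "Familial cancer of breast|Leigh syndrome"),
    (12705, "C", "T", "SNV", "rs2854122", "441150", "Benign",
     "Resistance to Parkinson disease"),
    (11719, "G", "A", "SNV", "rs2853495", "441151", "Benign",
     "Juvenile myopathy, encephalopathy, lactic acidosis and stroke"),
]
with open(DATA / "clinvar_synthetic.tsv", "w") as fh:
    fh.write("# synthetic ClinVar-style annotation table (frozen stand-in)\n")
    fh.write("pos\tref\talt\tvariant_type\trsid\tclinvar_id\tsignificance\tdiagnoses\n")
    for row in CLINVAR_ROWS:
        fh.write("\t".join(str(x) for x in row) + "\n")
print("clinvar rows:", len(CLINVAR_ROWS))

# ---------------------------------------------------------------- ancestral list
ANCESTRAL = [
    (750, "A", "G", "SNV"), (2706, "A", "G", "SNV"), (263, "A", "G", "SNV"),
    (15326, "A", "G", "SNV"), (9769, "T", "", "del"), (12272, "A", "", "del"),
]
with open(DATA / "ancestral_variants.tsv", "w") as fh:
    fh.write("pos\tref\talt\tvariant_type\n")
    for row in ANCESTRAL:
        fh.write("\t".join(str(x) for x in row) + "\n")
print("ancestral rows:", len(ANCESTRAL))
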