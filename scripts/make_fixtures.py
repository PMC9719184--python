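"""One-off generator for the shipped fixture TSVs (run from repo root)."""
from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "src" / "famscore" / "data"
OUT.mkdir(parents=True, exist_ok=True)

# (gene, subclass, protein_length, C-terminal architecture key)
# Lengths are plausible approximations; the table is a user-replaceable
# reconstruction, not an authoritative annotation.
FAMILY = [
    # C-I: RING + B-box + CC + COS + FN3 + SPRY
    ("MID1", "C-I", 667), ("MID2", "C-I", 705), ("TRIM9", "C-I", 710),
    ("TRIM36", "C-I", 728), ("TRIM46", "C-I", 759), ("TRIM67", "C-I", 783),
    # C-II: RING + B-box + CC + COS
    ("TRIM54", "C-II", 358), ("TRIM55", "C-II", 558), ("TRIM63", "C-II", 353),
    # C-III: RING + B-box + CC + COS + FN3
    ("TRIM42", "C-III", 723),
    # C-IV: RING + B-box + CC + PRY-SPRY (largest sub-class)
    ("TRIM4", "C-IV", 500), ("TRIM5", "C-IV", 493), ("TRIM6", "C-IV", 488),
    ("TRIM7", "C-IV", 511), ("TRIM10", "C-IV", 481), ("TRIM11", "C-IV", 468),
    ("TRIM15", "C-IV", 465), ("TRIM17", "C-IV", 477), ("TRIM21", "C-IV", 475),
    ("TRIM22", "C-IV", 498), ("TRIM25", "C-IV", 630), ("TRIM26", "C-IV", 539),
    ("TRIM27", "C-IV", 513), ("TRIM34", "C-IV", 488), ("TRIM35", "C-IV", 493),
    ("TRIM38", "C-IV", 465), ("TRIM39", "C-IV", 518), ("TRIM41", "C-IV", 630),
    ("TRIM43", "C-IV", 446), ("TRIM47", "C-IV", 638), ("TRIM48", "C-IV", 440),
    ("TRIM49", "C-IV", 452), ("TRIM49B", "C-IV", 452),
    ("TRIM50", "C-IV", 486), ("TRIM51", "C-IV", 452),
    ("TRIM58", "C-IV", 486), ("TRIM60", "C-IV", 471), ("TRIM62", "C-IV", 475),
    ("TRIM64", "C-IV", 449), ("TRIM64B", "C-IV", 449),
    ("TRIM65", "C-IV", 517), ("TRIM68", "C-IV", 485), ("TRIM69", "C-IV", 500),
    ("TRIM72", "C-IV", 477), ("TRIM75", "C-IV", 437), ("TRIM77", "C-IV", 490),
    ("MEFV", "C-IV", 781), ("TRIML1", "C-IV", 468),
    # C-V: RING + B-box + CC only
    ("TRIM8", "C-V", 551), ("PML", "C-V", 882), ("TRIM31", "C-V", 425),
    ("TRIM40", "C-V", 258), ("TRIM52", "C-V", 297), ("TRIM56", "C-V", 755),
    ("TRIM61", "C-V", 201), ("TRIM73", "C-V", 250), ("TRIM74", "C-V", 250),
    # C-VI: RING + B-box + CC + PHD + Bromodomain
    ("TRIM24", "C-VI", 1050), ("TRIM28", "C-VI", 835), ("TRIM33", "C-VI", 1127),
    ("TRIM66", "C-VI", 1216),
    # C-VII: RING + B-box + CC + FIL + NHL
    ("TRIM2", "C-VII", 744), ("TRIM3", "C-VII", 744), ("TRIM32", "C-VII", 653),
    ("TRIM71", "C-VII", 868),
    # C-VIII: RING + B-box + CC + MATH
    ("TRIM37", "C-VIII", 964),
    # C-IX: RING + B-box + CC + ARF
    ("TRIM23", "C-IX", 574),
    # C-X: RING + B-box + CC + FIL
    ("TRIM45", "C-X", 580),
    # C-XI: RING + B-box + CC + TM
    ("TRIM13", "C-XI", 407), ("TRIM59", "C-XI", 403),
    # UC: unclassified / RING-less members
    ("TRIM16", "UC", 564), ("TRIM14", "UC", 442), ("TRIM20", "UC", 400),
    ("TRIM29", "UC", 588), ("TRIM44", "UC", 344), ("TRIM76", "UC", 630),
    ("TRIML2", "UC", 454),
]
assert len(FAMILY) == 77, len(FAMILY)
assert len({g for g, _, _ in FAMILY}) == 77

CTERM = {
    "C-I": [("COS", 0.45, 0.52), ("FN3", 0.56, 0.68), ("SPRY", 0.72, 0.97)],
    "C-II": [("COS", 0.60, 0.75)],
    "C-III": [("COS", 0.45, 0.52), ("FN3", 0.56, 0.68)],
    "C-IV": [("PRY", 0.55, 0.65), ("SPRY", 0.67, 0.97)],
    "C-V": [],
    "C-VI": [("PHD", 0.72, 0.78), ("BROMO", 0.82, 0.95)],
    "C-VII": [("FIL", 0.45, 0.57), ("NHL", 0.62, 0.97)],
    "C-VIII": [("MATH", 0.55, 0.75)],
    "C-IX": [("ARF", 0.60, 0.92)],
    "C-X": [("FIL", 0.55, 0.75)],
    "C-XI": [("TM", 0.90, 0.97)],
    "UC": [("SPRY", 0.67, 0.97)],
}
# RING-less / atypical members keep only what is plausible
NO_RING = {"TRIM16", "TRIM14", "TRIM20", "TRIM29", "TRIM44", "TRIM76", "TRIML2"}
NO_CTERM_UC = {"TRIM29", "TRIM44", "TRIM76"}

rows = []
for gene, sub, L in FAMILY:
    doms = []
    if gene not in NO_RING:
        doms.append(("RING", 16, 16 + 44))
        doms.append(("BBOX", max(70, 16 + 50), max(70, 16 + 50) + 40))
    cc_start = int(0.25 * L)
    doms.append(("CC", cc_start, min(L, cc_start + max(60, int(0.12 * L)))))
    cterm = [] if gene in NO_CTERM_UC else CTERM[sub]
    for name, f0, f1 in cterm:
        s, e = max(1, int(f0 * L)), min(L, int(f1 * L))
        if s < e:
            doms.append((name, s, e))
    for name, s, e in doms:
        rows.append(f"{gene}\t{sub}\t{L}\t{name}\t{s}\t{e}")

header = (
    "# Reconstructed TRIM-family annotation (77 genes, 12 sub-classes).\n"
    "# Sub-class assignments follow the conventional C-terminal domain\n"
    "# architecture classification; protein lengths and domain coordinates\n"
    "# are plausible approximations, not an authoritative annotation.\n"
    "# Replace this file with your own table to analyze a different family.\n"
    "gene\tsubclass\tprotein_length\tdomain_name\tdomain_start\tdomain_end\n"
)
(OUT / "trim_family.tsv").write_text(header + "\n".join(rows) + "\n")

REGULATORS = {
    "antigen_presentation": [
        "HLA-A", "HLA-B", "HLA-C", "HLA-DPA1", "HLA-DPB1", "HLA-DQA1",
        "HLA-DQB1", "HLA-DRA", "HLA-DRB1", "HLA-E", "HLA-F", "HLA-G",
        "B2M", "TAP1", "TAP2", "TAPBP", "MICA", "MICB",
    ],
    "cell_adhesion": ["ICAM1", "ITGB2", "SELP"],
    "co_inhibitor": [
        "PDCD1", "CTLA4", "LAG3", "HAVCR2", "TIGIT", "BTLA", "CD274",
        "PDCD1LG2", "VTCN1", "CD160", "CD244", "ADORA2A", "IDO1", "VSIR",
        "KIR2DL1", "KIR2DL3",
    ],
    "co_stimulator": [
        "CD28", "ICOS", "CD40LG", "CD27", "TNFRSF4", "TNFRSF9", "TNFRSF14",
        "TNFRSF18", "CD226", "TMIGD2", "CD80", "CD86", "ICOSLG", "CD40",
        "CD70", "TNFSF4", "TNFSF9", "TNFSF14",
    ],
    "ligand": [
        "IL2", "IL4", "IL10", "IL12A", "IL13", "IL1B", "IFNG", "TNF",
        "TGFB1", "CXCL9", "CXCL10", "CCL5", "VEGFA", "VEGFB",
    ],
    "receptor": ["IL2RA", "IL10RA", "IL4R", "TGFBR1", "IFNGR1", "TNFRSF1A"],
    "other": ["ENTPD1", "NT5E", "HMGB1"],
}
lines = ["# Reconstructed immune-regulator panel (78 genes, 7 categories).",
         "# User-replaceable fixture.",
         "feature\tcategory"]
n = 0
for cat, genes in REGULATORS.items():
    for g in genes:
        lines.append(f"{g}\t{cat}")
        n += 1
assert n == 78, n
(OUT / "immune_regulators.tsv").write_text("\n".join(lines) + "\n")
print("wrote fixtures:", n, "regulators;", len(FAMILY), "family genes")
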