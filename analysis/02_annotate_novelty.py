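"""Novelty annotation of the Strigaibol family and module-skip alignment
of the shortened Dorothopsin A variants.

Each compound is compared with the curated reference database; known
compounds come back at distance 0, variants with their substitution
notation.  The 16-18-residue Dorothopsin A compounds are aligned on the
19-residue template to place their skipped modules.  Writes
results/annotations.tsv and results/skip_alignments.tsv.
"""

import pathlib

import pandas as pd

import peptaibiomics as pb
from peptaibiomics import annotate
from peptaibiomics import io as pio

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

sf1_table = pio.load_sf1_table()
db = pio.load_reference_fixture()

rows = []
for _, r in sf1_table[sf1_table["name"].str.startswith("Strigaibol")].iterrows():
    seq = pb.parse_sequence(r["sequence"], label=r["name"])
    ann = annotate.annotate_compound(seq, db)
    notation = (
        annotate.substitution_notation(ann.nearest[0][0], seq)
        if ann.nearest and ann.status != "known"
        else ""
    )
    rows.append(
        dict(name=r["name"], status=ann.status,
             nearest="; ".join(e.name for e, _ in ann.nearest),
             distance=ann.nearest[0][1] if ann.nearest else "",
             substitutions=notation)
    )
ann_df = pd.DataFrame(rows)
ann_df.to_csv(OUT / "annotations.tsv", sep="\t", index=False)
print(ann_df.groupby("status").size().to_string())

template = pb.parse_sequence(
    sf1_table[sf1_table["name"] == "Dorothopsin A-a I"]["sequence"].iloc[0],
    label="Dorothopsin A-a I",
)
skip_rows = []
short_names = [n for n in sf1_table["name"]
               if n.startswith(("Dorothopsin A-b", "Doothopsin A-c",
                                "Dorothopsin A-c", "Dorothopsin A-d",
                                "Dorothopsin A-e", "Dorothopsin A-f"))]
for name in short_names:
    seq = pb.parse_sequence(
        sf1_table[sf1_table["name"] == name]["sequence"].iloc[0], label=name
    ).without_gaps()
    sols = annotate.skip_alignment(seq, template)
    skip_rows.append(
        dict(name=name, length=seq.length(),
             gaps=",".join(map(str, sols[0].gap_positions)),
             n_substitutions=sols[0].n_substitutions,
             gapped=sols[0].gapped.token_string())
    )
skip_df = pd.DataFrame(skip_rows)
skip_df.to_csv(OUT / "skip_alignments.tsv", sep="\t", index=False)
print()
print("module-skip placements on the 19-residue template:")
print(skip_df[["name", "length", "gaps", "n_substitutions"]].to_string(index=False))
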