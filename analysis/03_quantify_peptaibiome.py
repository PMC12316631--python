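"""Peptaibiome composition per strain from the printed EIC percentages.

The printed per-compound peptaibiome shares are treated as areas (the
shares are scale-invariant, so this recovers the same composition) and
summed into class shares per strain: peptaibols vs short/medium/long
lipopeptaibols.  Writes results/peptaibiome_shares.tsv.
"""

import pathlib

import pandas as pd

import peptaibiomics as pb
from peptaibiomics import io as pio
from peptaibiomics.quantify import percentages, record_for

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

records = []
for fixture in (pio.load_sf1_table(), pio.load_lipopeptaibol_table()):
    for _, r in fixture.iterrows():
        if not r["pct_peptaibiome"] or pd.isna(r["pct_peptaibiome"]):
            continue
        seq = pb.parse_sequence(r["sequence"], label=r["name"])
        records.append(
            record_for(seq, r["strain"], float(r["pct_peptaibiome"]), name=r["name"])
        )

summary = percentages(records)
shares = summary.per_strain.round(2)
shares.to_csv(OUT / "peptaibiome_shares.tsv", sep="\t")
print("class shares of each strain's peptaibiome (%):")
print(shares.to_string())

ham = summary.per_compound.query(
    "strain == 'T. hamatum SZMC 28747' and compound_class == 'peptaibol'"
)
print()
print(f"T. hamatum peptaibol share: {ham['pct_peptaibiome'].sum():.2f}% "
      "(printed strain table: 23.62%)")
top = ham.nlargest(1, "pct_class").iloc[0]
print(f"most produced peptaibol: {top['compound']} at {top['pct_class']:.2f}% "
      "of the class (printed: 29.09%)")
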