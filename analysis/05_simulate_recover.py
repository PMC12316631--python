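"""De novo recovery of synthetic peptaibiomes across noise conditions.

Generates seeded SF1-family compounds, simulates their y-ion ladders over
a grid of mass-error and decoy densities, reads each ladder back de novo
and scores per-residue recovery against the ground truth.  Writes
results/recovery.tsv.
"""

import pathlib

import pandas as pd

from peptaibiomics import assembly, synthetic
from peptaibiomics.chemistry import default_library

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

lib = default_library()
GRID = [(0.0, 0.0), (3.0, 0.2), (5.0, 0.2), (10.0, 0.5), (25.0, 1.0)]
N = 60
SEED = 7

rows = []
for ppm, decoys in GRID:
    cfg = synthetic.SimulationConfig(
        n_compounds=N, seed=SEED, mass_error_ppm=ppm, decoy_per_100da=decoys
    )
    comps = synthetic.simulate_compounds(synthetic.sf1_template(), cfg)
    ok = total = exact = 0
    for i, (seq, _, _) in enumerate(comps):
        pk, _ = synthetic.ladder_spectrum(seq, "y", cfg, compound_index=i)
        sols = assembly.infer_from_ladder(pk, assembly.LadderParams(series="y"), lib)
        truth = seq.positions()
        total += len(truth)
        if sols and len(sols[0].inferred.positions()) == len(truth):
            hits = sum(1 for a, b in zip(truth, sols[0].inferred.positions()) if a == b)
            ok += hits
            exact += hits == len(truth)
    rows.append(
        dict(mass_error_ppm=ppm, decoy_per_100da=decoys, n_spectra=N,
             residue_recovery=round(ok / total, 4),
             exact_sequences=exact)
    )

df = pd.DataFrame(rows)
df.to_csv(OUT / "recovery.tsv", sep="\t", index=False)
print(df.to_string(index=False))
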