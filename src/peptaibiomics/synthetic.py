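"""Seeded generator of ground-truthed peptaibiomes: sequences, abundances
and MS2 spectra with the statistical structure the analysis assumes.

The shipped templates emulate the compound families of Trichoderma clade
Viride peptaibiomes:

- a 19-residue SF1 peptaibol family with the conserved
  Gln6-Aib7-Aib8-Aib9-Ser10-Lxx11-Aib12-Pro13-Vxx14 core and
  position-specific microheterogeneity elsewhere,
- octanoyl-capped lipopeptaibol families of 7, 11 and 15 residues built on
  the repetitive Vxx/Lxx-Aib-Gly motif.

Compound abundances are log-normal (a strain produces one to four dominant
variants and a long tail of minor ones); fragment m/z values carry
Gaussian relative (ppm) error; decoy peaks arrive Poisson-uniformly along
the m/z axis; fragment intensities follow a rank-decay law since observed
intensities are only used qualitatively.  Every draw is reproducible: one
seed per run, with per-compound substreams derived by counter so outputs
are independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import Peak, PeakList
from .chemistry import (
    PROTON,
    ResidueLibrary,
    SequenceModel,
    default_library,
    mh_plus,
    adduct_mz,
)
from .fragmentation import diagnostic_pair, ladder, water_loss, NoDiagnosticSiteError

__all__ = [
    "FamilyTemplate",
    "SimulationConfig",
    "sf1_template",
    "lipopeptaibol_template",
    "simulate_compounds",
    "simulate_spectrum",
    "ladder_spectrum",
    "standard_bundle",
]


@dataclass
class FamilyTemplate:
    """Position-specific residue alphabets of one compound family.

    ``alphabets[i]`` maps tokens to probabilities at position i+1 (they
    must sum to 1); ``terminus`` likewise for the amino alcohol.
    ``skip_probability`` is the per-compound probability of one module
    skip, drawn uniformly over ``skip_positions``.
    """

    name: str
    cap: str
    alphabets: list[dict[str, float]]
    terminus: dict[str, float]
    skip_probability: float = 0.0
    skip_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for i, alph in enumerate([*self.alphabets, self.terminus], start=1):
            if not alph:
                raise ValueError(f"{self.name}: empty alphabet at position {i}")
            s = sum(alph.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.name}: probabilities at position {i} sum to {s}, not 1"
                )

    @property
    def length(self) -> int:
        return len(self.alphabets) + 1


def _spread(major: str, minors: dict[str, float]) -> dict[str, float]:
    return {major: 1.0 - sum(minors.values()), **minors}


def sf1_template(substitution_rate: float = 0.15) -> FamilyTemplate:
    """19-residue SF1 peptaibol family with the conserved central motif.

    Positions 6-14 are fixed (probability 1); the variable N- and
    C-terminal positions substitute their major residue at
    ``substitution_rate``, split over the minor residues seen in this
    family (Vxx/Ala at 1-4, Gln/Glu at 17, Lxxol/Vxxol terminus).
    """
    r = substitution_rate
    if not 0 <= r < 1:
        raise ValueError("substitution_rate must be in [0, 1)")
    var = lambda major, *minors: _spread(
        major, {m: r / len(minors) for m in minors} if minors else {}
    )
    alphabets = [
        var("Aib", "Vxx"),          # 1
        var("Ser", "Ala", "Gly"),   # 2
        var("Aib", "Ala"),          # 3
        var("Aib", "Ala"),          # 4
        var("Lxx", "Vxx"),          # 5
        {"Gln": 1.0},               # 6  conserved core
        {"Aib": 1.0},               # 7
        {"Aib": 1.0},               # 8
        {"Aib": 1.0},               # 9
        {"Ser": 1.0},               # 10
        {"Lxx": 1.0},               # 11
        {"Aib": 1.0},               # 12
        {"Pro": 1.0},               # 13
        {"Vxx": 1.0},               # 14
        var("Aib", "Vxx"),          # 15
        var("Aib", "Lxx", "Vxx"),   # 16
        var("Gln", "Glu"),          # 17
        var("Gln", "Ala"),          # 18
    ]
    return FamilyTemplate(
        name="SF1",
        cap="Ac",
        alphabets=alphabets,
        terminus=var("Lxxol", "Vxxol"),
        skip_probability=0.0,
        skip_positions=(9, 16, 17),
    )


def lipopeptaibol_template(
    n_residues: int = 7, substitution_rate: float = 0.15
) -> FamilyTemplate:
    """Octanoyl-capped lipopeptaibol family of 7, 11 or 15 residues.

    Built on the Vxx/Lxx-Aib-Gly repeat with Gly spacers, as in the
    short/medium/long length classes of this clade's lipopeptaibols.
    """
    r = substitution_rate
    var = lambda major, *minors: _spread(
        major, {m: r / len(minors) for m in minors} if minors else {}
    )
    motif = [var("Lxx", "Vxx"), var("Aib", "Ala"), {"Gly": 1.0}]
    if n_residues == 7:
        alphabets = [var("Aib", "Vxx", "Ala"), {"Gly": 1.0}, *motif[:2],
                     {"Gly": 1.0}, var("Lxx", "Vxx")]
    elif n_residues == 11:
        alphabets = [var("Aib", "Vxx", "Ala"), {"Gly": 1.0}, *motif[:2],
                     {"Gly": 1.0}, {"Gly": 1.0}, *motif[:2], {"Gly": 1.0},
                     var("Lxx", "Vxx")]
    elif n_residues == 15:
        alphabets = [var("Aib", "Vxx", "Ala"), {"Gly": 1.0}, *motif[:2],
                     {"Gly": 1.0}, {"Gly": 1.0}, *motif[:2], {"Gly": 1.0},
                     {"Gly": 1.0}, *motif[:2], {"Gly": 1.0}, var("Lxx", "Vxx")]
    else:
        raise ValueError("lipopeptaibol templates come in 7/11/15 residues")
    return FamilyTemplate(
        name=f"lipopeptaibol-{n_residues}",
        cap="Oc",
        alphabets=alphabets,
        terminus={"Lxxol": 1.0},
    )


@dataclass
class SimulationConfig:
    """Knobs of the generator; the defaults are the study conditions.

    ``abundance_mu``/``abundance_sigma`` parameterise the log-normal
    compound abundances (sigma 1.5 gives the few-dominant/many-minor
    profile of observed peptaibiomes).  ``mass_error_ppm`` is the Gaussian
    sigma of relative m/z error (Orbitrap-like, a few ppm).
    ``decoy_per_100da`` is the expected number of uniform decoy peaks per
    100 Da of spectrum span.  ``intensity_decay`` is the rank-decay
    exponent of fragment intensities.  ``rt_range`` is the elution window
    in minutes.
    """

    n_compounds: int = 20
    seed: int = 0
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.5
    mass_error_ppm: float = 3.0
    decoy_per_100da: float = 0.2
    intensity_decay: float = 0.5
    adducts: tuple[str, ...] = ("M+H", "M+Na", "M+2H")
    rt_range: tuple[float, float] = (5.0, 55.0)
    water_loss_ions: bool = True

    def __post_init__(self) -> None:
        for name in ("abundance_sigma", "mass_error_ppm", "decoy_per_100da",
                     "intensity_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _rng(config: SimulationConfig, *counters: int) -> np.random.Generator:
    # counter-based substreams: independent of generation order
    return np.random.default_rng([config.seed, *counters])


def _draw(rng: np.random.Generator, alphabet: dict[str, float]) -> str:
    toks = sorted(alphabet)
    probs = np.array([alphabet[t] for t in toks])
    return toks[rng.choice(len(toks), p=probs / probs.sum())]


def simulate_compounds(
    template: FamilyTemplate,
    config: SimulationConfig,
) -> list[tuple[SequenceModel, float, float]]:
    """Draw a family of compounds: (sequence, abundance, rt) triples.

    Deterministic under (template, config, seed).  Retention times are
    uniform over ``rt_range`` with per-compound jitter and made distinct
    by construction; abundances are log-normal.
    """
    out = []
    lo, hi = config.rt_range
    for i in range(config.n_compounds):
        rng = _rng(config, 1, i)
        residues = [_draw(rng, a) for a in template.alphabets]
        terminus = _draw(rng, template.terminus)
        if template.skip_positions and rng.random() < template.skip_probability:
            pos = int(rng.choice(template.skip_positions))
            residues[pos - 1] = None  # deleted module
        residues = [r for r in residues if r is not None]
        abundance = float(rng.lognormal(config.abundance_mu, config.abundance_sigma))
        rt = float(lo + (hi - lo) * (i + rng.uniform(0.05, 0.95)) / config.n_compounds)
        seq = SequenceModel(
            cap=template.cap,
            residues=tuple(residues),
            terminus=terminus,
            label=f"{template.name} synthetic {i + 1}",
            rt=round(rt, 3),
        )
        out.append((seq, abundance, seq.rt))
    return out


def simulate_spectrum(
    seq: SequenceModel,
    config: SimulationConfig,
    compound_index: int = 0,
    library: ResidueLibrary | None = None,
) -> tuple[PeakList, list[dict]]:
    """Simulate the observed peak list of one compound, with ground truth.

    Emits precursor adducts, the diagnostic Aib-Pro b/y pair when the
    sequence contains a single Pro, full b/y ladders, and (optionally)
    water-loss companions of the y series; each theoretical m/z is
    perturbed by Gaussian relative error of ``mass_error_ppm``; decoys are
    added Poisson-uniformly over the m/z span.  The ground-truth list
    records every peak with its origin annotation ('decoy' for noise).
    """
    lib = library or default_library()
    rng = _rng(config, 2, compound_index)
    theoretical: list[tuple[float, str]] = []
    for adduct in config.adducts:
        theoretical.append((adduct_mz(seq, adduct, library=lib), f"precursor {adduct}"))
    try:
        b_ion, y_ion = diagnostic_pair(seq, lib)
        theoretical.append((b_ion.mz, f"diagnostic b{b_ion.index}"))
        theoretical.append((y_ion.mz, f"diagnostic y{y_ion.index}"))
    except (NoDiagnosticSiteError, ValueError):
        pass
    for series in ("b", "y"):
        for ion in ladder(seq, series, library=lib):
            theoretical.append((ion.mz, f"{series}{ion.index}"))
            if config.water_loss_ions and series == "y":
                lost = water_loss(ion)
                theoretical.append((lost.mz, f"y{ion.index}-H2O"))

    n_sig = len(theoretical)
    order = np.argsort([mz for mz, _ in theoretical])[::-1]
    ranks = np.empty(n_sig, dtype=int)
    ranks[order] = np.arange(1, n_sig + 1)
    peaks: list[Peak] = []
    truth: list[dict] = []
    for k, (mz, note) in enumerate(theoretical):
        obs = mz * (1.0 + rng.normal(0.0, config.mass_error_ppm) * 1e-6)
        intensity = float(1000.0 * ranks[k] ** (-config.intensity_decay))
        peaks.append(Peak(obs, intensity))
        truth.append(
            {"mz": obs, "theoretical_mz": mz, "annotation": note, "signal": True}
        )
    lo = min(mz for mz, _ in theoretical)
    hi = max(mz for mz, _ in theoretical)
    span = max(hi - lo, 1.0)
    n_decoys = int(rng.poisson(config.decoy_per_100da * span / 100.0))
    for mz in rng.uniform(lo, hi, size=n_decoys):
        intensity = float(1000.0 * rng.uniform(0.02, 0.3))
        peaks.append(Peak(float(mz), intensity))
        truth.append(
            {"mz": float(mz), "theoretical_mz": None, "annotation": "decoy",
             "signal": False}
        )
    peak_list = PeakList(
        peaks=peaks,
        precursor_mz=mh_plus(seq, lib),
        precursor_charge=1,
        title=seq.label or seq.token_string(),
        rt=seq.rt,
    )
    truth.sort(key=lambda t: t["mz"])
    return peak_list, truth


def ladder_spectrum(
    seq: SequenceModel,
    series: str,
    config: SimulationConfig,
    compound_index: int = 0,
    library: ResidueLibrary | None = None,
) -> tuple[PeakList, list[dict]]:
    """Simulate a clean single-series fragment ladder (plus noise/decoys).

    This is the canonical input of the de novo ladder reader: the full b-
    or y-ion ladder of one compound, each m/z perturbed by Gaussian ppm
    error, plus Poisson-uniform decoys.  The precursor is the true [M+H]+.
    """
    lib = library or default_library()
    rng = _rng(config, 3, compound_index)
    theoretical = [(ion.mz, f"{series}{ion.index}") for ion in ladder(seq, series, library=lib)]
    peaks: list[Peak] = []
    truth: list[dict] = []
    for k, (mz, note) in enumerate(theoretical):
        obs = mz * (1.0 + rng.normal(0.0, config.mass_error_ppm) * 1e-6)
        intensity = float(1000.0 * (k + 1) ** (-config.intensity_decay))
        peaks.append(Peak(obs, intensity))
        truth.append(
            {"mz": obs, "theoretical_mz": mz, "annotation": note, "signal": True}
        )
    lo, hi = min(p.mz for p in peaks), max(p.mz for p in peaks)
    span = max(hi - lo, 1.0)
    for mz in rng.uniform(lo, hi, size=int(rng.poisson(config.decoy_per_100da * span / 100.0))):
        peaks.append(Peak(float(mz), float(1000.0 * rng.uniform(0.02, 0.3))))
        truth.append(
            {"mz": float(mz), "theoretical_mz": None, "annotation": "decoy",
             "signal": False}
        )
    peak_list = PeakList(
        peaks=peaks,
        precursor_mz=mh_plus(seq, lib),
        precursor_charge=1,
        title=seq.label or seq.token_string(),
        rt=seq.rt,
    )
    truth.sort(key=lambda t: t["mz"])
    return peak_list, truth


def standard_bundle(
    seed: int = 0, n_per_family: int = 10
) -> dict[str, list[tuple[SequenceModel, float, float]]]:
    """The standard synthetic peptaibiome: one SF1 family plus 7/11/15-residue
    octanoyl lipopeptaibol families, as produced by the strains this kind of
    analysis targets."""
    out = {}
    families = [
        ("SF1", sf1_template()),
        ("lipo7", lipopeptaibol_template(7)),
        ("lipo11", lipopeptaibol_template(11)),
        ("lipo15", lipopeptaibol_template(15)),
    ]
    for salt, (key, template) in enumerate(families):
        config = SimulationConfig(n_compounds=n_per_family, seed=seed + 1000 * salt)
        out[key] = simulate_compounds(template, config)
    return out
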