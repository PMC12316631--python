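"""De novo sequence inference from observed fragment-ion ladders.

Consecutive peaks of a b- or y-ion ladder differ by exactly one residue
mass, so a chain of peaks whose gaps all match registered residue masses
spells out the sequence.  The low-mass end is anchored by the acyl cap
(b series) or the amino alcohol (y series); the gap between the largest
chained ion and the precursor closes the molecule.  Whatever terminal mass
cannot be assigned to any cap/alcohol/residue combination is reported as an
unexplained residual, displayed rounded to integer Da (the compound tables
print residuals like 145, 146, 160 or 222).

Matching tolerance defaults to max(5 ppm, 0.005 Da), appropriate for
Orbitrap data acquired at resolution 70,000.  Isobaric residues collapse to
their ambiguity codes (Leu/Ile -> Lxx, Val/Iva -> Vxx); Gln and Lys differ
by 0.036 Da and Gln/Glu by 0.984 Da, both resolvable at this tolerance.

The chain search is a deterministic longest-path search over the peak
graph with a small beam (width 5) on ties, ties broken by smaller
cumulative ppm error, then by lower starting m/z.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .chemistry import (
    PROTON,
    ResidueLibrary,
    SequenceModel,
    default_library,
)

__all__ = [
    "Peak",
    "PeakList",
    "LadderParams",
    "LadderSolution",
    "infer_from_ladder",
    "detect_repeat_unit",
    "group_positional_isomers",
]

DEFAULT_TOL_PPM = 5.0
DEFAULT_ABS_TOL_DA = 0.005
BEAM_WIDTH = 5


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 0.0


@dataclass
class PeakList:
    """A centroided spectrum: sorted peaks plus precursor information."""

    peaks: list[Peak]
    precursor_mz: float
    precursor_charge: int = 1
    title: str = ""
    rt: float | None = None

    def __post_init__(self) -> None:
        pk = [p if isinstance(p, Peak) else Peak(*p) for p in self.peaks]
        for p in pk:
            if not p.mz > 0:
                raise ValueError("peak m/z must be positive")
            if p.intensity < 0:
                raise ValueError("peak intensity must be non-negative")
            if p.mz != p.mz or p.intensity != p.intensity:
                raise ValueError("NaN in peak list")
        self.peaks = sorted(pk, key=lambda p: p.mz)

    @property
    def mzs(self) -> list[float]:
        return [p.mz for p in self.peaks]

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class LadderParams:
    """Matching parameters for ladder reading.

    ``tol_ppm`` is the per-peak relative mass accuracy (1-sigma-like);
    ``abs_tol_da`` an absolute floor for small m/z.  A ladder step is the
    *difference* of two measured peaks, so its window combines both peaks'
    budgets in quadrature, scaled by ``sigma_mult`` so that an 18-step
    ladder passes end-to-end with high probability.  Residues in the
    library are no closer than 0.94 Da apart, far above these windows, so
    widening costs no discrimination.
    """

    tol_ppm: float = DEFAULT_TOL_PPM
    abs_tol_da: float = DEFAULT_ABS_TOL_DA
    sigma_mult: float = 3.5
    series: str = "y"  # which ladder the peaks are interpreted as
    cap_candidates: tuple[str, ...] = ("Ac", "Oc")
    alcohol_candidates: tuple[str, ...] = (
        "Lxxol",
        "Vxxol",
        "Pheol",
        "Trpol",
        "Alaol",
        "Glyol",
    )

    def tol_at(self, mz: float) -> float:
        """Single-measurement window at one m/z."""
        return max(self.sigma_mult * self.tol_ppm * 1e-6 * mz, self.abs_tol_da)

    def pair_tol(self, mz_a: float, mz_b: float) -> float:
        """Window for the difference of two measured m/z values."""
        combined = (mz_a * mz_a + mz_b * mz_b) ** 0.5
        return max(self.sigma_mult * self.tol_ppm * 1e-6 * combined, self.abs_tol_da)


@dataclass
class LadderSolution:
    """One ranked interpretation of a fragment ladder."""

    inferred: SequenceModel
    direction: str  # 'b-ladder' | 'y-ladder'
    per_step_error_ppm: list[float]
    matched_peak_indices: list[int]
    score: float  # fraction of bonds explained, in [0, 1]
    unexplained_residual: float | None = None
    notes: str = ""

    @property
    def residual_display(self) -> int | None:
        """Residual rounded to integer Da, as printed in compound tables."""
        if self.unexplained_residual is None:
            return None
        return round(self.unexplained_residual)


def _match_internal(delta: float, tol: float, lib: ResidueLibrary) -> tuple[str, float] | None:
    """Best internal-residue match for a mass difference, or None.

    Returns the canonical (ambiguity-collapsed) token and the signed error.
    """
    best: tuple[str, float] | None = None
    seen: set[str] = set()
    for rd in lib:
        if rd.residue_class != "internal":
            continue
        tok = lib.canonical(rd.token)
        if tok in seen:
            continue
        seen.add(tok)
        err = delta - rd.mono_mass
        if abs(err) <= tol and (best is None or abs(err) < abs(best[1])):
            best = (tok, err)
    return best


def _chains(mzs: list[float], params: LadderParams, lib: ResidueLibrary):
    """Beam search for maximal residue-spaced chains over the peak graph."""
    n = len(mzs)
    edges: dict[int, list[tuple[int, str, float]]] = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            delta = mzs[j] - mzs[i]
            tol = params.pair_tol(mzs[i], mzs[j])
            if delta > 200:  # heavier than any registered residue
                break
            m = _match_internal(delta, tol, lib)
            if m is not None:
                edges[i].append((j, m[0], m[1] / mzs[j] * 1e6))

    # states: (chain of peak indices, tokens, ppm errors)
    best_chains: list[tuple[list[int], list[str], list[float]]] = []
    # longest chain ending at each node, kept as a small beam
    table: dict[int, list[tuple[list[int], list[str], list[float]]]] = {}
    for i in range(n):
        states = table.get(i, []) + [([i], [], [])]
        states.sort(key=lambda s: (-len(s[0]), sum(abs(e) for e in s[2]), s[0][0]))
        states = states[:BEAM_WIDTH]
        table[i] = states
        for j, tok, ppm in edges[i]:
            for chain, toks, errs in states:
                table.setdefault(j, []).append(
                    (chain + [j], toks + [tok], errs + [ppm])
                )
    for states in table.values():
        best_chains.extend(states)
    best_chains.sort(
        key=lambda s: (-len(s[0]), sum(abs(e) for e in s[2]), s[0][0])
    )
    return best_chains[: BEAM_WIDTH * 4]


def infer_from_ladder(
    peaks: PeakList,
    params: LadderParams | None = None,
    library: ResidueLibrary | None = None,
    max_solutions: int = 5,
) -> list[LadderSolution]:
    """Infer candidate sequences from one observed fragment ladder.

    The peak list is interpreted as the ``params.series`` ladder of a
    singly protonated molecule whose [M+H]+ is ``peaks.precursor_mz``.
    Solutions are ranked by the number of peaks explained, then score
    (fraction of bonds explained), then mean absolute ppm error; see the
    ranking comment below for why peak coverage leads.  No chainable path
    yields an empty list.
    """
    params = params or LadderParams()
    lib = library or default_library()
    if len(peaks) < 2:
        return []
    mzs = peaks.mzs
    if peaks.precursor_mz < mzs[-1] - params.tol_at(mzs[-1]):
        raise ValueError(
            f"precursor m/z {peaks.precursor_mz:.4f} below largest fragment "
            f"{mzs[-1]:.4f}: inconsistent input"
        )

    solutions = []
    for chain, toks, errs in _chains(mzs, params, lib):
        if len(chain) < 2:
            continue
        sol = _close_solution(chain, toks, errs, peaks, params, lib)
        if sol is not None:
            solutions.append(sol)
    # rank: most peaks explained first (isobaric residue lumpings such as
    # Aib+Aib = Lxx+Gly make peak-skipping interpretations internally
    # complete, so peak coverage is the discriminator), then score, then
    # mean |ppm| error; deduplicate by inferred token string
    solutions.sort(
        key=lambda s: (
            -len(s.matched_peak_indices),
            -s.score,
            (sum(abs(e) for e in s.per_step_error_ppm) / len(s.per_step_error_ppm))
            if s.per_step_error_ppm
            else 0.0,
        )
    )
    seen: set[str] = set()
    unique = []
    for s in solutions:
        key = s.inferred.token_string()
        if key not in seen:
            seen.add(key)
            unique.append(s)
    return unique[:max_solutions]


def _close_solution(
    chain: list[int],
    mid_tokens: list[str],
    errs: list[float],
    peaks: PeakList,
    params: LadderParams,
    lib: ResidueLibrary,
) -> LadderSolution | None:
    """Anchor a residue chain at both ends and assemble a SequenceModel."""
    mzs = peaks.mzs
    low = mzs[chain[0]]
    high = mzs[chain[-1]]
    precursor = peaks.precursor_mz

    if params.series == "y":
        # low end: y_k = sum(k-1 residues) + alcohol + proton.  Try pure
        # alcohol first, then alcohol plus up to two residues.
        bottom_tokens, bottom_residual = _explain_terminal(
            low - PROTON, params.alcohol_candidates, lib, params.tol_at(low)
        )
        # top end: [M+H]+ - y_max = cap + leading residues
        gap = precursor - high
        top_tokens, top_residual = _explain_leading(
            gap, params.cap_candidates, lib, params.pair_tol(high, precursor)
        )
        if bottom_tokens is None and top_tokens is None:
            return None
        cap = top_tokens[0] if top_tokens else params.cap_candidates[0]
        leading = list(top_tokens[1:]) if top_tokens else []
        if bottom_tokens is not None:
            terminus = bottom_tokens[-1]
            trailing = list(bottom_tokens[:-1])
            residual = None
        else:
            terminus = None
            trailing = []
            residual = bottom_residual
        # y ladders read C->N as m/z grows, so mid tokens reverse into
        # N->C order; 'trailing' are residues between the y anchor and the
        # alcohol
        residues = leading + list(reversed(mid_tokens)) + trailing
        unexplained = residual if bottom_tokens is None else (
            top_residual if top_tokens is None else None
        )
        direction = "y-ladder"
        explained = (
            len(mid_tokens)
            + (1 if bottom_tokens is not None else 0)
            + (1 if top_tokens is not None else 0)
        )
        total = len(mid_tokens) + 2
    elif params.series == "b":
        # low end: b_k = cap + sum(k residues) + proton
        bottom_tokens, bottom_residual = _explain_leading(
            low - PROTON, params.cap_candidates, lib, params.tol_at(low)
        )
        # top end: [M+H]+ - b_max = alcohol (+ trailing residues)
        gap = precursor - high
        top_tokens, top_residual = _explain_terminal(
            gap, params.alcohol_candidates, lib, params.pair_tol(high, precursor)
        )
        if bottom_tokens is None and top_tokens is None:
            return None
        cap = bottom_tokens[0] if bottom_tokens else params.cap_candidates[0]
        leading = list(bottom_tokens[1:]) if bottom_tokens else []
        if top_tokens is not None:
            terminus = top_tokens[-1]
            trailing = list(top_tokens[:-1])
            residual = None
        else:
            terminus = None
            trailing = []
            residual = top_residual
        residues = leading + list(mid_tokens) + trailing
        unexplained = residual if top_tokens is None else (
            bottom_residual if bottom_tokens is None else None
        )
        direction = "b-ladder"
        explained = (
            len(mid_tokens)
            + (1 if bottom_tokens is not None else 0)
            + (1 if top_tokens is not None else 0)
        )
        total = len(mid_tokens) + 2
    else:
        raise ValueError(f"series must be 'b' or 'y', got {params.series!r}")

    seq = SequenceModel(
        cap=cap,
        residues=tuple(residues),
        terminus=terminus,
        residual_mass=unexplained if terminus is None else None,
        label=peaks.title,
        rt=peaks.rt,
    )
    return LadderSolution(
        inferred=seq,
        direction=direction,
        per_step_error_ppm=errs,
        matched_peak_indices=chain,
        score=explained / total,
        unexplained_residual=unexplained,
    )


def _explain_terminal(
    mass: float,
    alcohols: tuple[str, ...],
    lib: ResidueLibrary,
    tol: float,
    max_extra: int = 2,
) -> tuple[tuple[str, ...] | None, float | None]:
    """Explain a C-terminal mass as (residues... , amino alcohol).

    Returns (token tuple ending in the alcohol, None) on success or
    (None, mass) when no combination fits and the mass becomes a residual.
    """
    internals = sorted(
        {lib.canonical(r.token) for r in lib if r.residue_class == "internal"}
    )
    best: tuple[float, tuple[str, ...]] | None = None
    for alc in alcohols:
        base = lib.residue_mass(alc)
        for k in range(max_extra + 1):
            for combo in itertools.combinations_with_replacement(internals, k):
                total = base + sum(lib.residue_mass(t) for t in combo)
                err = abs(mass - total)
                if err <= tol and (best is None or err < best[0]):
                    best = (err, tuple(combo) + (alc,))
    if best is None:
        return None, mass
    return best[1], None


def _explain_leading(
    mass: float,
    caps: tuple[str, ...],
    lib: ResidueLibrary,
    tol: float,
    max_extra: int = 2,
) -> tuple[tuple[str, ...] | None, float | None]:
    """Explain an N-terminal mass as (cap, residues...)."""
    internals = sorted(
        {lib.canonical(r.token) for r in lib if r.residue_class == "internal"}
    )
    best: tuple[float, tuple[str, ...]] | None = None
    for cap in caps:
        base = lib.residue_mass(cap)
        for k in range(max_extra + 1):
            for combo in itertools.combinations_with_replacement(internals, k):
                total = base + sum(lib.residue_mass(t) for t in combo)
                err = abs(mass - total)
                if err <= tol and (best is None or err < best[0]):
                    best = (err, (cap,) + tuple(combo))
    if best is None:
        return None, mass
    return best[1], None


def detect_repeat_unit(
    mzs: list[float] | PeakList,
    abs_tol_da: float = 0.05,
) -> list[tuple[float, int]]:
    """Recurring consecutive mass differences, with multiplicities >= 2.

    Unassignable spectra sometimes show repeating gaps (e.g. alternating
    72 and 127 Da) hinting at a polymeric or non-peptaibol backbone.
    Differences are binned at ``abs_tol_da``; the result is sorted by
    count (descending) then by the representative difference.
    """
    values = mzs.mzs if isinstance(mzs, PeakList) else sorted(mzs)
    if len(values) < 3:
        return []
    diffs = [b - a for a, b in zip(values, values[1:])]
    bins: list[list[float]] = []
    for d in sorted(diffs):
        if bins and d - bins[-1][0] <= abs_tol_da:
            bins[-1].append(d)
        else:
            bins.append([d])
    out = [
        (round(sum(b) / len(b), 4), len(b))
        for b in bins
        if len(b) >= 2
    ]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def group_positional_isomers(
    compounds: list[SequenceModel],
    rt_tol: float = 0.1,
) -> list[list[SequenceModel]]:
    """Group compounds with identical token strings but distinct rts.

    Such pairs are positional isomers in the field's sense: the token
    string cannot distinguish Leu/Ile or Val/Iva, so identical strings
    eluting at different retention times are distinct isomeric compounds.
    Members closer than ``rt_tol`` minutes are merged as duplicates.
    Within each group, members are sorted by rt.
    """
    if any(c.rt is None for c in compounds):
        raise ValueError("all compounds need a retention time for isomer grouping")
    by_string: dict[str, list[SequenceModel]] = {}
    for c in compounds:
        by_string.setdefault(c.token_string(), []).append(c)
    groups = []
    for members in by_string.values():
        members.sort(key=lambda c: c.rt)
        merged: list[SequenceModel] = []
        for m in members:
            if merged and abs(m.rt - merged[-1].rt) <= rt_tol:
                continue  # duplicate observation of the same compound
            merged.append(m)
        groups.append(merged)
    return groups
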