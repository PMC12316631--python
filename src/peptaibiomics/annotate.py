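"""Novelty assessment against a reference sequence database.

A newly sequenced compound is compared position-by-position with
equal-length reference peptaibiotics; ambiguity codes match their members
(Lxx matches Leu and Ile).  Differences are written in the field's
substitution notation, e.g. ``[Aib]^1 -> [Vxx]^1; [Aib]^8 -> [Ala]^8``,
with the terminal amino alcohol counting as a position.  Shorter compounds
are reconciled with a longer template by *skip alignment*: nonribosomal
peptide synthetases occasionally skip a module, deleting one residue, and
the skipped template positions are rendered as gaps.  Compounds are named
with a family stem plus a Roman numeral in order of elution.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .chemistry import GAP, ResidueLibrary, SequenceModel, default_library

__all__ = [
    "ReferenceEntry",
    "Annotation",
    "SkipSolution",
    "nearest_reference",
    "substitution_notation",
    "skip_alignment",
    "assign_names",
    "roman",
    "annotate_compound",
]

logger = logging.getLogger(__name__)

MAX_SKIPS = 3  # largest observed module-skip deficit


@dataclass(frozen=True)
class ReferenceEntry:
    """One reference peptaibiotic: a named, fully resolved sequence."""

    name: str
    sequence: SequenceModel
    organism: str = ""
    citation: str = ""


@dataclass
class Annotation:
    """Novelty verdict for one compound."""

    status: str  # 'known' | 'positional_isomer' | 'new'
    nearest: list[tuple[ReferenceEntry, int]] = field(default_factory=list)
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    skip_positions: list[int] = field(default_factory=list)
    assigned_name: str = ""

    @property
    def distance(self) -> int:
        return len(self.substitutions) + len(self.skip_positions)


def _positions(seq: SequenceModel) -> tuple[str, ...]:
    return seq.positions()


def _diff(
    ref: tuple[str, ...],
    obs: tuple[str, ...],
    lib: ResidueLibrary,
) -> list[tuple[int, str, str]]:
    """Position-wise substitutions between equal-length token strings."""
    if len(ref) != len(obs):
        raise ValueError(
            f"length mismatch ({len(ref)} vs {len(obs)}); use skip_alignment "
            "to reconcile sequences of different length"
        )
    out = []
    for i, (a, b) in enumerate(zip(ref, obs), start=1):
        if not lib.equivalent(a, b):
            out.append((i, a, b))
    return out


def nearest_reference(
    seq: SequenceModel,
    db: list[ReferenceEntry],
    max_dist: int | None = None,
    library: ResidueLibrary | None = None,
) -> list[tuple[ReferenceEntry, list[tuple[int, str, str]]]]:
    """Minimal-substitution matches among equal-length references.

    All co-minimal references are returned, ordered alphabetically by
    name.  ``max_dist`` caps the acceptable distance; an empty list means
    nothing within reach (or no equal-length reference at all).
    """
    if not db:
        raise ValueError("reference database is empty")
    lib = library or default_library()
    obs = _positions(seq)
    hits = []
    for entry in db:
        ref = _positions(entry.sequence)
        if len(ref) != len(obs):
            continue
        subs = _diff(ref, obs, lib)
        hits.append((entry, subs))
    if not hits:
        return []
    dmin = min(len(s) for _, s in hits)
    if max_dist is not None and dmin > max_dist:
        return []
    out = [(e, s) for e, s in hits if len(s) == dmin]
    out.sort(key=lambda h: h[0].name)
    return out


def substitution_notation(
    ref: SequenceModel | ReferenceEntry,
    obs: SequenceModel,
    library: ResidueLibrary | None = None,
) -> str:
    """Display string ``[REF]^i -> [OBS]^i; ...`` in ascending position order.

    Empty string for identity.  Arrow rendered with the unicode arrow used
    in the field's tables.
    """
    lib = library or default_library()
    rseq = ref.sequence if isinstance(ref, ReferenceEntry) else ref
    subs = _diff(_positions(rseq), _positions(obs), lib)
    return "; ".join(f"[{a}]^{i} → [{b}]^{i}" for i, a, b in subs)


def is_compositional_isomer(
    ref: SequenceModel, obs: SequenceModel, library: ResidueLibrary | None = None
) -> bool:
    """True when ref and obs share the same token multiset but not order.

    Such pairs (written with a swap arrow in the field's tables) are
    flagged separately from position-wise substitutions.
    """
    lib = library or default_library()
    a = sorted(lib.canonical(t) if t != GAP else GAP for t in _positions(ref))
    b = sorted(lib.canonical(t) if t != GAP else GAP for t in _positions(obs))
    return a == b and _positions(ref) != _positions(obs)


@dataclass(frozen=True)
class SkipSolution:
    """One gap placement of a shorter sequence on a longer template."""

    gap_positions: tuple[int, ...]  # 1-based template positions
    substitutions: tuple[tuple[int, str, str], ...]
    gapped: SequenceModel

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)


def skip_alignment(
    short_seq: SequenceModel,
    template_seq: SequenceModel,
    max_skips: int = MAX_SKIPS,
    library: ResidueLibrary | None = None,
) -> list[SkipSolution]:
    """Place module-skip gaps so a shorter compound aligns on a template.

    All placements of the length deficit are enumerated; placements
    minimising the substitution count are returned.  Deleting any one
    position of a run of identical template residues yields the same
    alignment, and such degenerate placements are collapsed onto the
    rightmost position of the run (matching how the compound tables print
    e.g. ``Aib-Aib-(skip)-Ser`` for a skipped Aib in an Aib triplet).
    Remaining ties are broken by the total absolute mass difference of the
    substituted residue pairs, then by the leftmost gap vector; all
    solutions co-minimal after the mass tie-break are returned, the
    canonical choice first.
    """
    lib = library or default_library()
    obs = _positions(short_seq)
    tpl = _positions(template_seq)
    deficit = len(tpl) - len(obs)
    if deficit <= 0:
        raise ValueError(
            f"short sequence ({len(obs)}) is not shorter than template ({len(tpl)})"
        )
    if deficit > max_skips:
        raise ValueError(
            f"length deficit {deficit} exceeds the module-skip cap "
            f"({max_skips}); raise max_skips explicitly to force the search"
        )
    candidates: dict[tuple[str, ...], tuple[tuple[int, ...], tuple]] = {}
    for gaps in itertools.combinations(range(1, len(tpl) + 1), deficit):
        kept = tuple(t for i, t in enumerate(tpl, start=1) if i not in gaps)
        # score substitutions in template coordinates
        subs = []
        obs_positions = [i for i in range(1, len(tpl) + 1) if i not in gaps]
        for i, o in zip(obs_positions, obs):
            t = tpl[i - 1]
            if not lib.equivalent(t, o):
                subs.append((i, t, o))
        key = kept
        prev = candidates.get(key)
        if prev is None or gaps > prev[0]:
            candidates[key] = (gaps, tuple(subs))

    def mass_penalty(subs) -> float:
        total = 0.0
        for _, a, b in subs:
            total += abs(lib.residue_mass(a) - lib.residue_mass(b))
        return total

    scored = sorted(
        candidates.values(),
        key=lambda gs: (len(gs[1]), mass_penalty(gs[1]), gs[0]),
    )
    best_subs = len(scored[0][1])
    best_mass = mass_penalty(scored[0][1])
    out = []
    for gaps, subs in scored:
        if len(subs) != best_subs or mass_penalty(subs) - best_mass > 1e-9:
            break
        out.append(
            SkipSolution(
                gap_positions=gaps,
                substitutions=subs,
                gapped=short_seq.with_gaps_at(
                    [g for g in gaps if g <= len(tpl) - 1]
                ),
            )
        )
    return out


_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"),
    (100, "C"), (90, "XC"), (50, "L"), (40, "XL"),
    (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def roman(n: int) -> str:
    """Roman numeral for a positive integer."""
    if n <= 0:
        raise ValueError("Roman numerals start at 1")
    out = []
    for val, sym in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


def assign_names(
    compounds: list[SequenceModel],
    stem: str,
) -> list[str]:
    """Name compounds ``<stem> I, II, ...`` in ascending elution order.

    The stem is the closest identified compound family for sequence
    variants, or a producer-species-derived name for wholly new groups;
    choosing it is the caller's job.  Duplicate retention times keep their
    input order (a warning is logged).
    """
    if not stem:
        raise ValueError("group stem must be non-empty")
    if any(c.rt is None for c in compounds):
        raise ValueError("all compounds need a retention time for naming")
    order = sorted(range(len(compounds)), key=lambda i: (compounds[i].rt, i))
    rts = [compounds[i].rt for i in order]
    if len(set(rts)) != len(rts):
        logger.warning("duplicate retention times in %s group; input order kept", stem)
    names = [""] * len(compounds)
    for rank, i in enumerate(order, start=1):
        names[i] = f"{stem} {roman(rank)}"
    return names


def annotate_compound(
    seq: SequenceModel,
    db: list[ReferenceEntry],
    max_dist: int | None = None,
    library: ResidueLibrary | None = None,
) -> Annotation:
    """Full novelty verdict for one compound against a reference set.

    Distance 0 -> known; otherwise new, with the co-minimal nearest
    references and the substitution list of the first (alphabetical) one.
    Positional-isomer status (identical string, different rt) is a
    relationship between co-produced compounds, not against the database,
    and is assigned by the caller via
    :func:`peptaibiomics.assembly.group_positional_isomers`.
    """
    hits = nearest_reference(seq, db, max_dist=max_dist, library=library)
    if not hits:
        return Annotation(status="new", nearest=[])
    dist = len(hits[0][1])
    status = "known" if dist == 0 else "new"
    return Annotation(
        status=status,
        nearest=[(e, len(s)) for e, s in hits],
        substitutions=list(hits[0][1]),
    )
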