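"""Allele-specific (ARMS) primer design over an allele alignment.

An ARMS primer discriminates alleles through its 3'-terminal base: extension
fails when the terminus mismatches the template, so product formation reports
the presence of one specific variant. Interior polymorphic positions are not
discriminating and are covered with IUPAC "wobble" codes so that the primer
anneals to every known allele.

Conventions
-----------
* Sequences are written 5'->3' as synthesized.
* Reference coordinates are 1-based inclusive. Forward primers have
  ``ref_start <= ref_end``; reverse primers are printed with descending
  coordinates (``ref_start > ref_end``). For both orientations the 3'
  terminus sits at ``ref_end`` — that is the discriminated site.
* ``discriminating_bases`` are primer-strand bases (what the oligo ends in);
  the reference-sense variant a primer reports is its complement for reverse
  primers (:meth:`ArmsPrimer.template_base`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from statistics import fmean
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from . import _iupac
from ._iupac import (
    bases_of,
    complement_base,
    expand,
    expansion_count,
    iupac_for,
    reverse_complement,
)
from .allele_panel import AllelePanel, PolymorphicSite, find_polymorphic_sites

__all__ = [
    "ArmsPrimer",
    "DesignConstraints",
    "PrimerPanel",
    "ScreenReport",
    "expand_degenerate",
    "tm_estimate",
    "degenerate_tm",
    "design_allele_specific_primers",
    "complementarity_screen",
    "matches_template",
    "read_primer_table",
    "write_primer_table",
]

logger = logging.getLogger(__name__)

Orientation = Literal["forward", "reverse"]


@dataclass(frozen=True)
class ArmsPrimer:
    """One allele-specific oligo.

    A *split* primer has a concrete 3' base and a single discriminating base;
    a *combined* primer carries a degenerate 3' code whose expansion is the
    allele-discrimination set (one oligo pool standing for several alleles).
    """

    label: str
    orientation: Orientation
    sequence: str
    ref_start: int
    ref_end: int
    discriminating_bases: frozenset[str]

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"{self.label}: bad orientation {self.orientation!r}")
        for i, c in enumerate(self.sequence):
            if c not in _iupac.IUPAC_TO_BASES:
                raise ValueError(
                    f"{self.label}: invalid IUPAC code {c!r} at position {i + 1}"
                )
        span = abs(self.ref_end - self.ref_start) + 1
        if span != len(self.sequence):
            raise ValueError(
                f"{self.label}: reference span {self.ref_start}-{self.ref_end} "
                f"covers {span} positions but the sequence is "
                f"{len(self.sequence)} nt"
            )
        if self.orientation == "forward" and self.ref_start > self.ref_end:
            raise ValueError(f"{self.label}: forward primer with descending span")
        if not self.discriminating_bases:
            raise ValueError(f"{self.label}: empty discrimination set")

    # ------------------------------------------------------------ geometry
    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def site(self) -> int:
        """Reference position of the 3'-terminal (discriminating) base."""
        return self.ref_end

    @property
    def footprint(self) -> tuple[int, int]:
        """(low, high) reference interval covered, both ends inclusive."""
        return (min(self.ref_start, self.ref_end), max(self.ref_start, self.ref_end))

    # ------------------------------------------------------------- alleles
    @property
    def is_split(self) -> bool:
        return len(self.discriminating_bases) == 1

    @property
    def template_base(self) -> str:
        """Reference-sense base this (split) primer reports at its site."""
        if not self.is_split:
            raise ValueError(
                f"{self.label}: combined primer discriminates "
                f"{sorted(self.discriminating_bases)}; split it first"
            )
        (b,) = self.discriminating_bases
        return b if self.orientation == "forward" else complement_base(b)

    def template_bases(self) -> frozenset[str]:
        """Reference-sense bases covered by the discrimination set."""
        if self.orientation == "forward":
            return self.discriminating_bases
        return frozenset(complement_base(b) for b in self.discriminating_bases)

    def split(self) -> list["ArmsPrimer"]:
        """One single-base primer per member of the discrimination set."""
        if self.is_split:
            return [self]
        out = []
        for b in sorted(self.discriminating_bases):
            stem = self.label.split(" ")[0]
            out.append(
                replace(
                    self,
                    label=f"{stem} {b.lower()}",
                    sequence=self.sequence[:-1] + b,
                    discriminating_bases=frozenset(b),
                )
            )
        return out

    def reference_sense_sequence(self) -> str:
        """The primer's footprint written in reference (top-strand) sense."""
        if self.orientation == "forward":
            return self.sequence
        return reverse_complement(self.sequence)


def matches_template(primer: ArmsPrimer, template: str) -> bool:
    """Would this primer anneal perfectly to *template* (a full reference-length
    top-strand sequence) at its footprint, 3' terminus included?

    Degenerate primer positions match any base in their IUPAC set, so a
    wobbled interior never blocks annealing; the 3' code must cover the
    template base for extension to proceed (the ARMS principle).
    """
    lo, hi = primer.footprint
    if hi > len(template) or lo < 1:
        return False
    window = template[lo - 1 : hi]
    ref_sense = primer.reference_sense_sequence()
    return all(b in bases_of(c) for c, b in zip(ref_sense, window))


@dataclass(frozen=True)
class DesignConstraints:
    """Tunable design rules.

    The melting-temperature window defaults to 55 +/- 3 degC, the standard
    target for multiplexed allele-specific panels at this locus; run-length
    complementarity thresholds are heuristic screen defaults and fully
    configurable.
    """

    tm_target_c: float = 55.0
    tm_tolerance_c: float = 3.0
    min_length: int = 14
    max_length: int = 28
    max_self_complement_run: int = 8
    max_pair_complement_run: int = 8
    max_3prime_dimer_run: int = 4
    tm_method: Literal["nn", "wallace"] = "nn"

    def __post_init__(self) -> None:
        if self.tm_tolerance_c <= 0:
            raise ValueError("tm_tolerance_c must be positive")
        if not 8 <= self.min_length <= self.max_length:
            raise ValueError("need 8 <= min_length <= max_length")


class PrimerPanel:
    """A set of ARMS primers, optionally bound to the alignment they target."""

    def __init__(self, primers: Iterable[ArmsPrimer],
                 reference: AllelePanel | None = None):
        self.primers: tuple[ArmsPrimer, ...] = tuple(primers)
        labels = [p.label for p in self.primers]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate primer labels: {dupes}")
        self.reference = reference
        self._by_label = {p.label: p for p in self.primers}
        if reference is not None:
            self._check_against_reference(reference)

    def _check_against_reference(self, reference: AllelePanel) -> None:
        for p in self.primers:
            if not any(matches_template(p, a.sequence) for a in reference):
                raise ValueError(
                    f"primer {p.label!r} matches no allele in the reference panel"
                )

    def __len__(self) -> int:
        return len(self.primers)

    def __iter__(self):
        return iter(self.primers)

    def __getitem__(self, label: str) -> ArmsPrimer:
        return self._by_label[label]

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.primers)

    def forwards(self) -> list[ArmsPrimer]:
        return [p for p in self.primers if p.orientation == "forward"]

    def reverses(self) -> list[ArmsPrimer]:
        return [p for p in self.primers if p.orientation == "reverse"]

    def subset(self, labels: Iterable[str]) -> "PrimerPanel":
        return PrimerPanel((self._by_label[l] for l in labels), self.reference)


def expand_degenerate(primer: ArmsPrimer | str) -> list[str]:
    """All concrete A/C/G/T expansions of a degenerate primer sequence.

    The count equals the product of per-position IUPAC cardinalities; order
    is deterministic lexicographic.
    """
    seq = primer.sequence if isinstance(primer, ArmsPrimer) else primer
    return expand(seq)


def tm_estimate(sequence: str, method: Literal["nn", "wallace"] = "nn") -> float:
    """Melting temperature of a concrete oligo, in degC.

    ``"nn"`` uses the unified nearest-neighbour parameter set (50 mM Na+,
    default strand concentrations); ``"wallace"`` is the 2(A+T)+4(G+C) rule,
    exact integer arithmetic convenient for tests. Monotone non-decreasing in
    GC count at fixed length under both.
    """
    if len(sequence) < 8:
        raise ValueError(f"sequence too short for a Tm estimate ({len(sequence)} < 8)")
    bad = set(sequence) - _iupac.CONCRETE
    if bad:
        raise ValueError(f"tm_estimate needs a concrete A/C/G/T sequence, got {sorted(bad)}")
    if method == "wallace":
        return float(_mt.Tm_Wallace(sequence))
    return float(_mt.Tm_NN(sequence))


_MAX_TM_EXPANSIONS = 1024


def degenerate_tm(sequence: str, method: Literal["nn", "wallace"] = "nn"
                  ) -> tuple[float, float, float]:
    """(min, mean, max) Tm over the expansions of a degenerate sequence.

    A wobbled oligo pool has no single melting temperature; design decisions
    use the mean. Pools beyond 1024 expansions are summarized over the first
    1024 in lexicographic order (deterministic).
    """
    exps = expand(sequence)[:_MAX_TM_EXPANSIONS]
    tms = [tm_estimate(e, method) for e in exps]
    return (min(tms), fmean(tms), max(tms))


# --------------------------------------------------------------------------
# complementarity screening
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenReport:
    """Outcome of a self- or pair-complementarity screen."""

    passed: bool
    max_run: int
    run_offsets: tuple[int, int]  # 0-based (i in p, j in q) where the run starts
    three_prime_run: int
    reasons: tuple[str, ...] = ()


def _comp_matrix_runs(p: str, q_rc: str) -> tuple[int, tuple[int, int], int]:
    """Longest degenerate-compatible match between p and reverse-complemented q.

    Positions are compatible when their IUPAC sets intersect, i.e. at least
    one expansion of each could pair. Returns (longest run, offsets of its
    start, longest run ending at p's 3' terminus).
    """
    np_, nq = len(p), len(q_rc)
    best, best_at = 0, (0, 0)
    three = 0
    prev = [0] * (nq + 1)
    for i in range(1, np_ + 1):
        cur = [0] * (nq + 1)
        for j in range(1, nq + 1):
            if _iupac.compatible(p[i - 1], q_rc[j - 1]):
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
                    best_at = (i - cur[j], j - cur[j])
                if i == np_:
                    three = max(three, cur[j])
        prev = cur
    return best, best_at, three


def complementarity_screen(p: ArmsPrimer | str, q: ArmsPrimer | str | None = None,
                           constraints: DesignConstraints | None = None
                           ) -> ScreenReport:
    """Screen a primer against itself (hairpin/self-dimer) or a partner.

    Fails when the longest reverse-complement-compatible run exceeds
    ``max_pair_complement_run`` (``max_self_complement_run`` for self), or
    when a run anchored at the 3' terminus exceeds ``max_3prime_dimer_run``
    (3'-anchored duplexes are extensible and prime artefacts). Degenerate
    positions count as complementary if any of their expansions would pair,
    so the screen is conservative over the whole oligo pool.
    """
    constraints = constraints or DesignConstraints()
    ps = p.sequence if isinstance(p, ArmsPrimer) else p
    self_mode = q is None
    qs = ps if self_mode else (q.sequence if isinstance(q, ArmsPrimer) else q)
    limit = (constraints.max_self_complement_run if self_mode
             else constraints.max_pair_complement_run)
    run, at, three = _comp_matrix_runs(ps, reverse_complement(qs))
    reasons = []
    if run > limit:
        kind = "self" if self_mode else "pair"
        reasons.append(
            f"{kind}-complementary run of {run} nt (limit {limit}) at offsets {at}"
        )
    if three > constraints.max_3prime_dimer_run:
        reasons.append(
            f"3'-anchored complementary run of {three} nt "
            f"(limit {constraints.max_3prime_dimer_run})"
        )
    return ScreenReport(not reasons, run, at, three, tuple(reasons))


# --------------------------------------------------------------------------
# design
# --------------------------------------------------------------------------

def _ref_sense_window(panel: AllelePanel, poly: dict[int, PolymorphicSite],
                      lo: int, hi: int, site: int, site_base: str) -> str:
    """Reference-sense primer footprint [lo, hi] with wobbles at interior
    polymorphic columns and *site_base* fixed at the discriminated site."""
    out = []
    for pos in range(lo, hi + 1):
        if pos == site:
            out.append(site_base)
        elif pos in poly:
            out.append(iupac_for(poly[pos].observed_bases))
        else:
            out.append(panel.column(pos)[0])
    return "".join(out)


def design_allele_specific_primers(
    panel: AllelePanel,
    site: PolymorphicSite | int,
    orientation: Orientation,
    constraints: DesignConstraints | None = None,
    *,
    fallback_closest: bool = False,
    screen: bool = True,
) -> list[ArmsPrimer]:
    """Design one split ARMS primer per observed base at a polymorphic site.

    Each primer ends (3') exactly on the site, carrying one of its observed
    bases; every interior polymorphic position in the footprint is wobbled so
    the primer anneals to all known alleles. The length is the shortest one in
    ``[min_length, max_length]`` whose mean-over-expansions Tm falls within
    the target window. Primers failing the self-complementarity screen are
    dropped with a logged reason; a site/base with no feasible length yields
    no primer (logged), never an exception.

    With ``fallback_closest=True`` an out-of-window site/base instead gets the
    length whose mean Tm is closest to the target — useful when a simulation
    pipeline must guarantee full site coverage.
    """
    constraints = constraints or DesignConstraints()
    poly = {s.position: s for s in find_polymorphic_sites(panel)}
    pos = site.position if isinstance(site, PolymorphicSite) else int(site)
    if pos not in poly:
        raise ValueError(f"position {pos} is not polymorphic in this panel")
    site_obj = poly[pos]

    lo_t = constraints.tm_target_c - constraints.tm_tolerance_c
    hi_t = constraints.tm_target_c + constraints.tm_tolerance_c
    prefix = "F" if orientation == "forward" else "R"
    out: list[ArmsPrimer] = []
    for base in sorted(site_obj.observed_bases):
        chosen = None
        closest: tuple[float, int, str] | None = None
        for length in range(constraints.min_length, constraints.max_length + 1):
            if orientation == "forward":
                lo, hi = pos - length + 1, pos
            else:
                lo, hi = pos, pos + length - 1
            if lo < 1 or hi > panel.alignment_length:
                break
            ref_sense = _ref_sense_window(panel, poly, lo, hi, pos, base)
            seq = ref_sense if orientation == "forward" else reverse_complement(ref_sense)
            _, mean_tm, _ = degenerate_tm(seq, constraints.tm_method)
            if lo_t <= mean_tm <= hi_t:
                chosen = (length, seq)
                break
            gap = abs(mean_tm - constraints.tm_target_c)
            if closest is None or gap < closest[0]:
                closest = (gap, length, seq)
        if chosen is None and fallback_closest and closest is not None:
            chosen = (closest[1], closest[2])
        if chosen is None:
            logger.warning(
                "site %d base %s (%s): no length in [%d, %d] reaches Tm "
                "%.1f±%.1f degC; no primer designed",
                pos, base, orientation, constraints.min_length,
                constraints.max_length, constraints.tm_target_c,
                constraints.tm_tolerance_c,
            )
            continue
        length, seq = chosen
        primer_base = base if orientation == "forward" else complement_base(base)
        primer = ArmsPrimer(
            label=f"{prefix}{pos} {primer_base.lower()}",
            orientation=orientation,
            sequence=seq,
            ref_start=pos - length + 1 if orientation == "forward" else pos + length - 1,
            ref_end=pos,
            discriminating_bases=frozenset(primer_base),
        )
        if screen:
            report = complementarity_screen(primer, None, constraints)
            if not report.passed:
                logger.warning("dropping %s: %s", primer.label, "; ".join(report.reasons))
                continue
        out.append(primer)
    return out


# --------------------------------------------------------------------------
# TSV dialect (tab-separated, header row, '#' comments)
# --------------------------------------------------------------------------

_COLUMNS = ["label", "orientation", "sequence", "ref_start", "ref_end"]


def _discrimination_from_label(label: str, sequence: str) -> frozenset[str]:
    """Discrimination set from a label suffix like 'c/t' or 'ac'; falls back
    to the 3'-terminal code's expansion when the label has no suffix."""
    parts = label.split(None, 1)
    if len(parts) == 2:
        suffix = parts[1].replace("/", "")
        bases = frozenset(suffix.upper())
        if bases <= _iupac.CONCRETE and bases:
            return bases
    return bases_of(sequence[-1])


def read_primer_table(path: str | Path, reference: AllelePanel | None = None,
                      coord_policy: Literal["strict", "anchor3"] = "strict"
                      ) -> PrimerPanel:
    """Read a primer panel from the tab-separated dialect.

    Columns: label, orientation, sequence, ref_start, ref_end. The
    coordinate/length invariant (|ref_end - ref_start| + 1 == len(sequence))
    is checked on load. ``coord_policy="anchor3"`` repairs a violating row by
    keeping the 3' coordinate (ref_end) and re-deriving ref_start from the
    sequence length — useful for published tables with typographic span
    errors; ``"strict"`` raises naming the row.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"primer table {path}: missing columns {missing}")
    primers = []
    for _, row in df.iterrows():
        label = row["label"].strip()
        orientation = row["orientation"].strip().lower()
        seq = row["sequence"].strip().upper()
        start, end = int(row["ref_start"]), int(row["ref_end"])
        span = abs(end - start) + 1
        if span != len(seq):
            if coord_policy == "strict":
                raise ValueError(
                    f"row {label!r}: span {start}-{end} covers {span} positions "
                    f"but sequence is {len(seq)} nt"
                )
            start = end - len(seq) + 1 if orientation == "forward" else end + len(seq) - 1
        primers.append(
            ArmsPrimer(
                label=label,
                orientation=orientation,  # type: ignore[arg-type]
                sequence=seq,
                ref_start=start,
                ref_end=end,
                discriminating_bases=_discrimination_from_label(label, seq),
            )
        )
    return PrimerPanel(primers, reference)


def write_primer_table(panel: PrimerPanel, path: str | Path) -> None:
    """Write a panel in the tab-separated dialect (round-trips with the reader)."""
    df = pd.DataFrame(
        [
            {
                "label": p.label,
                "orientation": p.orientation,
                "sequence": p.sequence,
                "ref_start": p.ref_start,
                "ref_end": p.ref_end,
            }
            for p in panel
        ],
        columns=_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def design_full_panel(panel: AllelePanel,
                      constraints: DesignConstraints | None = None,
                      *, fallback_closest: bool = True,
                      screen: bool = False) -> PrimerPanel:
    """Design split primers at every polymorphic site, both orientations.

    Simulation-pipeline defaults: closest-Tm fallback on and screening off,
    so a random backbone cannot silently lose coverage of a site; a site
    orientation is skipped only when its footprint would leave the alignment.
    """
    constraints = constraints or DesignConstraints()
    primers: list[ArmsPrimer] = []
    for s in find_polymorphic_sites(panel):
        for orientation in ("forward", "reverse"):
            primers.extend(
                design_allele_specific_primers(
                    panel, s, orientation, constraints,
                    fallback_closest=fallback_closest, screen=screen,
                )
            )
    return PrimerPanel(primers, panel)
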