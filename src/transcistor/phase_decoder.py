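"""Decode bead readouts into haplotypes via cis-constraint assembly.

Positivity follows the assay's two QC rules: a cell must clear both the
event-count threshold (default 100 events) and the reporter/background
fluorescence ratio (default 4x), and a reaction counts as positive only when
*both* beads representing it — forward-anchored and reverse-anchored — are
positive. Each positive double-ARMS reaction asserts that two site variants
lie on the same chromosome (cis); the decoder collects these pairwise
constraints into a phase graph and two-colours the heterozygous sites into
the individual's one or two constituent haplotypes.

Failure modes are statuses, not exceptions: ``conflicted`` when constraint
support ties or a cycle is inconsistent, ``ambiguous`` when heterozygous
sites fall in disconnected phase components.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .assay_sim import MAX_AMPLICON_MULTIPLEX, ReactionReadout
from .primer_design import ArmsPrimer, PrimerPanel

__all__ = [
    "PositivityRule",
    "PhaseConstraint",
    "GenotypeCalls",
    "DecodedResult",
    "build_phase_graph",
    "call_positive",
    "genotype_from_positives",
    "extract_constraints",
    "assemble_haplotypes",
    "decode_individual",
    "brute_force_oracle",
]

GAP = "-"


@dataclass(frozen=True)
class PositivityRule:
    """Cell- and reaction-level positivity thresholds (inclusive bounds)."""

    min_events: int = 100
    min_reporter_ratio: float = 4.0
    require_both_beads: bool = True

    def __post_init__(self) -> None:
        if self.min_events <= 0 or self.min_reporter_ratio <= 0:
            raise ValueError("positivity thresholds must be positive")


@dataclass(frozen=True)
class PhaseConstraint:
    """cis(allele_a @ site_a, allele_b @ site_b), with reaction support."""

    site_a: int
    site_b: int
    allele_a: str
    allele_b: str
    support: int = 1

    def __post_init__(self) -> None:
        if not self.site_a < self.site_b:
            raise ValueError("constraint sites must satisfy site_a < site_b")
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass(frozen=True)
class GenotypeCalls:
    """Per-site base calls (unphased) plus the sites with no positive coverage."""

    calls: Mapping[int, tuple[str, ...]]
    missing: tuple[int, ...] = ()

    def het_sites(self) -> list[int]:
        return sorted(s for s, b in self.calls.items() if len(b) == 2)

    def hom_sites(self) -> list[int]:
        return sorted(s for s, b in self.calls.items() if len(b) == 1)

    def overcalled_sites(self) -> list[int]:
        return sorted(s for s, b in self.calls.items() if len(b) > 2)


@dataclass(frozen=True)
class DecodedResult:
    """One individual's decode: status ok | ambiguous | conflicted.

    ``haplotypes`` holds 1 (fully homozygous) or 2 site->base maps when phase
    could be assembled; sites whose phase or genotype could not be determined
    are simply absent from the maps (rendered as gaps by
    :meth:`haplotype_strings`).
    """

    status: str
    haplotypes: tuple[Mapping[int, str], ...]
    genotype_calls: GenotypeCalls
    diagnostics: tuple[str, ...] = ()

    def haplotype_strings(self, site_order: Sequence[int]) -> tuple[str, ...]:
        return tuple(
            "".join(h.get(s, GAP) for s in site_order) for h in self.haplotypes
        )

    def unordered_pair(self) -> frozenset:
        """Hashable order-free representation for comparisons against truth."""
        maps = self.haplotypes if len(self.haplotypes) == 2 else self.haplotypes * 2
        return frozenset(Counter(tuple(sorted(h.items())) for h in maps).items())


# --------------------------------------------------------------------------
# positivity and constraint extraction
# --------------------------------------------------------------------------

def _tube_reactions(panel: PrimerPanel, labels: Iterable[str],
                    max_amplicon_len: int) -> list[tuple[ArmsPrimer, ArmsPrimer]]:
    """The (forward, reverse) primer pairs that constitute reactions in a tube:
    both primers present, forward strictly upstream, product length legal."""
    present = [panel[l] for l in labels if l in panel]
    fwds = [p for p in present if p.orientation == "forward"]
    revs = [p for p in present if p.orientation == "reverse"]
    out = []
    for f in fwds:
        f_lo, f_hi = f.footprint
        for r in revs:
            r_lo, r_hi = r.footprint
            if f_hi < r_lo and (r_hi - f_lo + 1) <= max_amplicon_len:
                out.append((f, r))
    return out


def call_positive(readout: ReactionReadout, rule: PositivityRule,
                  panel: PrimerPanel,
                  max_amplicon_len: int = MAX_AMPLICON_MULTIPLEX
                  ) -> set[tuple[str, str]]:
    """Positive (forward, reverse) reactions in one tube.

    A cell passes iff events >= min_events AND reporter_ratio >=
    min_reporter_ratio; a reaction (f, r) is positive iff both its duplicate
    cells — (bead f, label r) and (bead r, label f) — pass (the both-beads
    rule; with ``require_both_beads=False`` one passing cell suffices).
    """
    pass_matrix = (readout.events >= rule.min_events) & (
        readout.reporter_ratio >= rule.min_reporter_ratio
    )
    positives = set()
    for f, r in _tube_reactions(panel, readout.primer_labels, max_amplicon_len):
        try:
            i, j = readout.index_of(f.label), readout.index_of(r.label)
        except KeyError as err:
            raise ValueError(
                f"reaction ({f.label}, {r.label}) is missing a duplicate cell "
                f"in tube {readout.tube_id}"
            ) from err
        cells = (pass_matrix[i, j], pass_matrix[j, i])
        ok = all(cells) if rule.require_both_beads else any(cells)
        if ok:
            positives.add((f.label, r.label))
    return positives


def genotype_from_positives(positives: Iterable[tuple[str, str]],
                            panel: PrimerPanel,
                            min_base_support: int = 1) -> GenotypeCalls:
    """Per-site base sets implied by which allele-specific reactions fired.

    A site's call is the union of the reference-sense discriminated bases of
    its primers appearing in any positive reaction, via either orientation.
    ``min_base_support`` demands that many independent positive reactions per
    base before it is called — each variant is tested against multiple
    partner sites, so on redundant layouts a genuine base collects support
    from every partner while a stray false capture rarely exceeds one.
    Sites of the reference panel with zero (surviving) positive coverage are
    recorded as missing, never silently dropped; sites with more than two
    bases are left in the calls for the assembler to flag as conflicted.
    """
    support: Counter[tuple[int, str]] = Counter()
    for f_label, r_label in positives:
        for label in (f_label, r_label):
            p = panel[label]
            support[(p.site, p.template_base)] += 1
    bases: dict[int, set[str]] = {}
    for (site, base), n in support.items():
        if n >= min_base_support:
            bases.setdefault(site, set()).add(base)
    calls = {s: tuple(sorted(b)) for s, b in bases.items()}
    covered_sites = {p.site for p in panel}
    missing = tuple(sorted(covered_sites - set(calls)))
    return GenotypeCalls(calls=calls, missing=missing)


def extract_constraints(positives: Iterable[tuple[str, str]],
                        panel: PrimerPanel) -> list[PhaseConstraint]:
    """Aggregate positive reactions into supported cis constraints.

    Support counts independent positive reactions (e.g. the same site pair
    observed in two tubes, or through different primer pairs) asserting the
    same cis relationship.
    """
    counts: Counter[tuple[int, str, int, str]] = Counter()
    for f_label, r_label in positives:
        f, r = panel[f_label], panel[r_label]
        sa, ba = f.site, f.template_base
        sb, bb = r.site, r.template_base
        if sa > sb:  # cannot happen for fwd-upstream reactions, kept defensive
            sa, ba, sb, bb = sb, bb, sa, ba
        counts[(sa, ba, sb, bb)] += 1
    return [
        PhaseConstraint(sa, sb, ba, bb, support=n)
        for (sa, ba, sb, bb), n in sorted(counts.items())
    ]


def build_phase_graph(constraints: Iterable[PhaseConstraint]) -> nx.Graph:
    """Graph with (site, base) nodes and support-weighted cis edges."""
    g = nx.Graph()
    for c in constraints:
        a, b = (c.site_a, c.allele_a), (c.site_b, c.allele_b)
        if g.has_edge(a, b):
            g[a][b]["support"] += c.support
        else:
            g.add_edge(a, b, support=c.support)
    return g


# --------------------------------------------------------------------------
# haplotype assembly
# --------------------------------------------------------------------------

def _pair_orientations(constraints: Iterable[PhaseConstraint],
                       het: Mapping[int, tuple[str, str]], strict: bool
                       ) -> tuple[dict[tuple[int, int], int], list[str], bool]:
    """Per het-site-pair phase orientation by support-weighted majority.

    Orientation +1 (coupling) pairs the lexicographically first bases of the
    two sites on one haplotype; -1 (repulsion) crosses them. Ties, or any
    disagreement in strict mode, flag a conflict.
    """
    votes: dict[tuple[int, int], list[int]] = {}
    for c in constraints:
        if c.site_a in het and c.site_b in het:
            a1, _ = het[c.site_a]
            b1, _ = het[c.site_b]
            coupling = (c.allele_a == a1) == (c.allele_b == b1)
            tally = votes.setdefault((c.site_a, c.site_b), [0, 0])
            tally[0 if coupling else 1] += c.support
    orientations: dict[tuple[int, int], int] = {}
    diagnostics: list[str] = []
    conflicted = False
    for pair, (cv, rv) in sorted(votes.items()):
        if cv and rv:
            diagnostics.append(
                f"sites {pair}: conflicting phase evidence "
                f"(coupling support {cv}, repulsion support {rv})"
            )
            if strict or cv == rv:
                conflicted = True
                continue
        orientations[pair] = 1 if cv >= rv else -1
    return orientations, diagnostics, conflicted


def assemble_haplotypes(constraints: Iterable[PhaseConstraint] | nx.Graph,
                        genotype_calls: GenotypeCalls,
                        *, strict: bool = False) -> DecodedResult:
    """Two-colour the heterozygous sites into the two haplotypes.

    Seeded at the lexicographically smallest heterozygous site (haplotype
    labels are arbitrary; compare results as unordered pairs), assignments
    propagate along cis edges; homozygous sites are copied onto both
    haplotypes. Site pairs with conflicting evidence are resolved by
    support-weighted majority (ties, or any conflict in ``strict`` mode, give
    status ``conflicted``), followed by a global consistency re-check over
    cycles. Heterozygous sites unreachable from the seed's phase component
    give status ``ambiguous`` with the disconnected blocks listed.
    """
    if isinstance(constraints, nx.Graph):
        constraint_list = []
        for u, v, d in constraints.edges(data=True):
            (sa, ba), (sb, bb) = sorted((u, v))
            constraint_list.append(
                PhaseConstraint(sa, sb, ba, bb, support=d["support"])
            )
    else:
        constraint_list = list(constraints)

    diagnostics: list[str] = []
    over = genotype_calls.overcalled_sites()
    if over:
        for s in over:
            diagnostics.append(
                f"site {s}: {len(genotype_calls.calls[s])} bases called "
                f"({'/'.join(genotype_calls.calls[s])}); a diploid carries at most 2"
            )
        return DecodedResult("conflicted", (), genotype_calls, tuple(diagnostics))

    # constraints must agree with the genotype calls: an edge naming a base
    # the calls do not carry (e.g. filtered low-support noise) is discarded
    kept = []
    for c in constraint_list:
        ca = genotype_calls.calls.get(c.site_a)
        cb = genotype_calls.calls.get(c.site_b)
        if ca and cb and c.allele_a in ca and c.allele_b in cb:
            kept.append(c)
    if len(kept) != len(constraint_list):
        diagnostics.append(
            f"discarded {len(constraint_list) - len(kept)} constraint(s) "
            "inconsistent with the genotype calls"
        )
    constraint_list = kept

    hom = {s: genotype_calls.calls[s][0] for s in genotype_calls.hom_sites()}
    het = {s: genotype_calls.calls[s] for s in genotype_calls.het_sites()}
    if genotype_calls.missing:
        diagnostics.append(
            f"no positive coverage at sites {list(genotype_calls.missing)}; "
            "decoded haplotypes carry gaps there"
        )

    if not het:
        hap = dict(hom)
        return DecodedResult("ok", (hap,), genotype_calls, tuple(diagnostics))

    orientations, conflict_diags, conflicted = _pair_orientations(
        constraint_list, het, strict
    )
    diagnostics.extend(conflict_diags)
    if conflicted:
        return DecodedResult("conflicted", (), genotype_calls, tuple(diagnostics))

    # two-colouring with parity propagation; edge orientation +1 keeps the
    # first bases of both sites together, -1 crosses them.
    g = nx.Graph()
    g.add_nodes_from(het)
    for (a, b), o in orientations.items():
        g.add_edge(a, b, orientation=o)

    seed = min(het)
    colour: dict[int, int] = {}
    for comp in nx.connected_components(g):
        if seed not in comp:
            continue
        colour[seed] = 0
        for u, v in nx.bfs_edges(g, seed):
            o = g[u][v]["orientation"]
            expected = colour[u] if o == 1 else 1 - colour[u]
            colour[v] = expected
        # global consistency re-check over every edge (catches odd cycles)
        for u, v, d in g.subgraph(comp).edges(data=True):
            expected = colour[u] if d["orientation"] == 1 else 1 - colour[u]
            if colour[v] != expected:
                diagnostics.append(
                    f"sites ({u}, {v}): phase cycle inconsistent with "
                    "majority orientations"
                )
                return DecodedResult(
                    "conflicted", (), genotype_calls, tuple(diagnostics)
                )

    unreached = [s for s in het if s not in colour]
    hap1 = dict(hom)
    hap2 = dict(hom)
    for s, c in colour.items():
        first, second = het[s]
        hap1[s] = first if c == 0 else second
        hap2[s] = second if c == 0 else first

    if unreached:
        blocks = [
            sorted(comp) for comp in nx.connected_components(g) if seed not in comp
        ]
        diagnostics.append(
            f"heterozygous sites in disconnected phase blocks: {blocks}"
        )
        return DecodedResult(
            "ambiguous", (hap1, hap2), genotype_calls, tuple(diagnostics)
        )

    return DecodedResult("ok", (hap1, hap2), genotype_calls, tuple(diagnostics))


def decode_individual(readouts: Iterable[ReactionReadout], panel: PrimerPanel,
                      rule: PositivityRule | None = None,
                      max_amplicon_len: int = MAX_AMPLICON_MULTIPLEX,
                      *, min_base_support: int = 1,
                      strict: bool = False) -> DecodedResult:
    """Full decode of one individual from its per-tube readouts."""
    rule = rule or PositivityRule()
    positives: list[tuple[str, str]] = []
    for readout in readouts:
        positives.extend(sorted(call_positive(readout, rule, panel,
                                              max_amplicon_len)))
    calls = genotype_from_positives(positives, panel, min_base_support)
    constraints = extract_constraints(positives, panel)
    return assemble_haplotypes(constraints, calls, strict=strict)


# --------------------------------------------------------------------------
# exhaustive oracle
# --------------------------------------------------------------------------

MAX_ORACLE_HET = 12


def _backbone(panel: PrimerPanel) -> str:
    """Reference-length template built from per-column majority bases."""
    ref = panel.reference
    if ref is None:
        raise ValueError("oracle needs a primer panel bound to its allele panel")
    cols = []
    for pos in range(1, ref.alignment_length + 1):
        col = ref.column(pos)
        cols.append(Counter(col).most_common(1)[0][0])
    return "".join(cols)


def brute_force_oracle(genotype_calls: GenotypeCalls,
                       positives: Iterable[tuple[str, str]],
                       panel: PrimerPanel,
                       max_amplicon_len: int = MAX_AMPLICON_MULTIPLEX
                       ) -> set[frozenset]:
    """All phase configurations consistent with the observed positive set.

    Enumerates every 2^(h-1) assignment of the h heterozygous sites, predicts
    the zero-noise positive reaction set of each candidate haplotype pair by
    direct primer-template matching, and keeps the candidates whose predicted
    set equals the observed one. The decoder must return the unique survivor
    when exactly one remains, and report ambiguity when several do. Refuses
    h > 12 (combinatorial guard).

    Returns a set of unordered haplotype pairs, each pair a frozenset of
    site-map item-tuples (a Counter-items frozenset so homozygous pairs
    survive the collapse).
    """
    from .primer_design import matches_template  # local to avoid cycle noise

    observed = frozenset(positives)
    het_sites = genotype_calls.het_sites()
    h = len(het_sites)
    if h > MAX_ORACLE_HET:
        raise ValueError(f"{h} heterozygous sites exceed the oracle guard of "
                         f"{MAX_ORACLE_HET}")
    if genotype_calls.overcalled_sites():
        return set()

    template = _backbone(panel)
    hom = {s: genotype_calls.calls[s][0] for s in genotype_calls.hom_sites()}

    reactions = _tube_reactions(panel, [p.label for p in panel], max_amplicon_len)

    match_cache: dict[str, frozenset[str]] = {}

    def matched_labels(hap: Mapping[int, str]) -> frozenset[str]:
        seq = list(template)
        for s, b in {**hom, **hap}.items():
            seq[s - 1] = b
        key = "".join(seq)
        if key not in match_cache:
            match_cache[key] = frozenset(
                p.label for p in panel if matches_template(p, key)
            )
        return match_cache[key]

    def predicted_positives(h1: Mapping[int, str], h2: Mapping[int, str]
                            ) -> frozenset[tuple[str, str]]:
        out = set()
        for hap in (h1, h2):
            m = matched_labels(hap)
            out.update(
                (f.label, r.label) for f, r in reactions
                if f.label in m and r.label in m
            )
        return frozenset(out)

    survivors: set[frozenset] = set()
    if h == 0:
        if predicted_positives({}, {}) == observed:
            pair_key = frozenset(
                Counter([tuple(sorted(hom.items()))] * 2).items()
            )
            survivors.add(pair_key)
        return survivors

    first = het_sites[0]
    rest = het_sites[1:]
    for flips in product((0, 1), repeat=h - 1):
        h1 = {first: genotype_calls.calls[first][0]}
        h2 = {first: genotype_calls.calls[first][1]}
        for s, flip in zip(rest, flips):
            b1, b2 = genotype_calls.calls[s]
            h1[s], h2[s] = (b1, b2) if flip == 0 else (b2, b1)
        if predicted_positives(h1, h2) == observed:
            full1 = tuple(sorted({**hom, **h1}.items()))
            full2 = tuple(sorted({**hom, **h2}.items()))
            survivors.add(frozenset(Counter([full1, full2]).items()))
    return survivors
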