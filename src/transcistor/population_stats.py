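"""Cohort aggregation: allele-frequency tables and linkage disequilibrium.

Two LD estimators are provided for the same pair of biallelic sites:

* ``composite_ld`` — the composite disequilibrium coefficient computable from
  unphased diploid genotypes,

      Delta = (1/n)[2 N_AABB + N_AABb + N_AaBB + N_AaBb/2] - 2 p_A p_B,

  which equals half the sample covariance of the two per-individual allele
  counts; its correlation uses denominator terms (p_A(1-p_A) + D_A) with
  D_A = P_AA - p_A^2 the within-locus Hardy-Weinberg departure (a simple
  denominator without the D terms is selectable).

* ``direct_ld`` — the gametic estimator from phased chromosomes,
  D = p_AB - p_A p_B, r = D / sqrt(p_A(1-p_A) p_B(1-p_B)).

Under random union of gametes the two agree in expectation; directly
determined haplotypes remove the inflation that Hardy-Weinberg departures
induce in the composite estimate.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .allele_panel import AllelePanel, find_polymorphic_sites, match_haplotype
from .phase_decoder import DecodedResult

__all__ = [
    "FrequencyTable",
    "LDResult",
    "LDCompareReport",
    "frequency_table",
    "carriers_by_count",
    "top_k_cumulative",
    "composite_ld",
    "direct_ld",
    "ld_compare",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyTable:
    """Allele counts and percent frequencies over a diploid cohort.

    Each individual contributes exactly two chromosomes; a homozygote
    contributes its allele twice. Frequencies are reported to one decimal in
    percent (raw counts are carried alongside, so rounding never drifts the
    arithmetic).
    """

    table: pd.DataFrame  # allele_name, chromosome_count, frequency_percent
    n_individuals: int
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"allele_name", "chromosome_count", "frequency_percent"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"frequency table missing columns {sorted(missing)}")
        total = float(self.table["frequency_percent"].sum())
        if abs(total - 100.0) > 0.5:
            raise ValueError(
                f"frequencies sum to {total:.1f}%, outside 100 +/- 0.5"
            )

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n_individuals

    @property
    def n_alleles(self) -> int:
        return len(self.table)

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], n_individuals: int,
                    excluded: Iterable[str] = ()) -> "FrequencyTable":
        n_chrom = 2 * n_individuals
        if sum(counts.values()) != n_chrom:
            raise ValueError(
                f"chromosome counts sum to {sum(counts.values())}, "
                f"expected {n_chrom} for {n_individuals} individuals"
            )
        rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        df = pd.DataFrame(
            {
                "allele_name": [k for k, _ in rows],
                "chromosome_count": [v for _, v in rows],
                "frequency_percent": [
                    round(100.0 * v / n_chrom, 1) for _, v in rows
                ],
            }
        )
        return cls(df, n_individuals, tuple(excluded))

    @classmethod
    def from_percentages(cls, names: Sequence[str], percents: Sequence[float],
                         n_individuals: int) -> "FrequencyTable":
        """Reconstruct integer chromosome counts from printed percentages
        (count = round(pct/100 x 2n)), the convention for published tables."""
        n_chrom = 2 * n_individuals
        counts = [int(round(p / 100.0 * n_chrom)) for p in percents]
        df = pd.DataFrame(
            {
                "allele_name": list(names),
                "chromosome_count": counts,
                "frequency_percent": [float(p) for p in percents],
            }
        )
        return cls(df, n_individuals)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def frequency_table(cohort_calls: Mapping[str, DecodedResult],
                    panel: AllelePanel) -> FrequencyTable:
    """Tabulate a decoded cohort against the known-allele panel.

    Haplotypes matching no panel allele are assigned deterministic
    ``NOVEL-NNN`` names in first-seen order under sorted individual IDs.
    Individuals with conflicted/ambiguous status (or gapped haplotypes) are
    excluded, logged, and n adjusted.
    """
    sites = find_polymorphic_sites(panel)
    positions = [s.position for s in sites]
    counts: Counter[str] = Counter()
    excluded: list[str] = []
    novel_names: dict[tuple, str] = {}
    for ind_id in sorted(cohort_calls):
        result = cohort_calls[ind_id]
        if result.status != "ok":
            logger.info("excluding %s: status %s", ind_id, result.status)
            excluded.append(ind_id)
            continue
        haps = result.haplotypes if len(result.haplotypes) == 2 \
            else result.haplotypes * 2
        names = []
        try:
            for hap in haps:
                if any(p not in hap for p in positions):
                    raise ValueError("gapped haplotype")
                report = match_haplotype(panel, hap)
                if report.status == "match":
                    names.append(report.allele)
                elif report.status == "novel":
                    key = tuple(sorted((p, hap[p]) for p in positions))
                    if key not in novel_names:
                        novel_names[key] = f"NOVEL-{len(novel_names) + 1:03d}"
                    names.append(novel_names[key])
                else:
                    raise ValueError(
                        f"panel cannot discriminate {report.candidates}"
                    )
        except ValueError as err:
            logger.info("excluding %s: %s", ind_id, err)
            excluded.append(ind_id)
            continue
        counts.update(names)
    n = len(cohort_calls) - len(excluded)
    if n == 0:
        raise ValueError("no decodable individuals in the cohort")
    return FrequencyTable.from_counts(counts, n, excluded)


def carriers_by_count(table: FrequencyTable, k_chromosomes: int) -> int:
    """Number of alleles observed on exactly *k* chromosomes in the cohort."""
    return int((table.table["chromosome_count"] == k_chromosomes).sum())


def top_k_cumulative(table: FrequencyTable, k: int) -> float:
    """Summed percent frequency of the k most common alleles."""
    if k > table.n_alleles:
        raise ValueError(f"k={k} exceeds the {table.n_alleles} alleles present")
    top = table.table["frequency_percent"].nlargest(k)
    return round(float(top.sum()), 1)


# --------------------------------------------------------------------------
# linkage disequilibrium
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LDResult:
    p_A: float
    p_B: float
    D: float
    r: float
    mode: str  # "composite" | "direct"
    p_AB: float | None = None  # direct mode only


def _check_polymorphic(p: float, label: str) -> None:
    if not 0.0 < p < 1.0:
        raise ValueError(
            f"site {label} is monomorphic in this cohort (p={p}); "
            "disequilibrium is undefined"
        )


def composite_ld(counts_a: Sequence[int], counts_b: Sequence[int],
                 denominator: str = "composite") -> LDResult:
    """Composite LD from unphased per-individual allele counts (0/1/2).

    ``denominator="composite"`` includes the within-locus HWE-departure terms
    D_A, D_B (the coefficient's standard form, bounding |r| by 1);
    ``"simple"`` uses plain p(1-p) factors.
    """
    na = np.asarray(counts_a, dtype=float)
    nb = np.asarray(counts_b, dtype=float)
    if na.shape != nb.shape or na.ndim != 1:
        raise ValueError("genotype count vectors must be 1-D and aligned")
    n = na.size
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if not (set(np.unique(na)) <= {0.0, 1.0, 2.0}
            and set(np.unique(nb)) <= {0.0, 1.0, 2.0}):
        raise ValueError("genotype counts must be 0, 1 or 2")
    p_a = na.mean() / 2.0
    p_b = nb.mean() / 2.0
    _check_polymorphic(p_a, "A")
    _check_polymorphic(p_b, "B")
    # Delta = (1/n)[2 N22 + N21 + N12 + N11/2] - 2 pA pB  (= cov(na, nb)/2)
    n22 = float(((na == 2) & (nb == 2)).sum())
    n21 = float(((na == 2) & (nb == 1)).sum())
    n12 = float(((na == 1) & (nb == 2)).sum())
    n11 = float(((na == 1) & (nb == 1)).sum())
    delta = (2.0 * n22 + n21 + n12 + 0.5 * n11) / n - 2.0 * p_a * p_b
    if denominator == "composite":
        d_a = float((na == 2).mean()) - p_a**2
        d_b = float((nb == 2).mean()) - p_b**2
        var_a = p_a * (1 - p_a) + d_a
        var_b = p_b * (1 - p_b) + d_b
    elif denominator == "simple":
        var_a = p_a * (1 - p_a)
        var_b = p_b * (1 - p_b)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if var_a <= 0 or var_b <= 0:
        raise ValueError("degenerate denominator; cohort carries no variance")
    r = delta / np.sqrt(var_a * var_b)
    return LDResult(p_A=float(p_a), p_B=float(p_b), D=float(delta),
                    r=float(r), mode="composite")


def direct_ld(gametes_a: Sequence[int], gametes_b: Sequence[int]) -> LDResult:
    """Gametic LD from phased chromosomes (0/1 indicators per chromosome)."""
    xa = np.asarray(gametes_a, dtype=float)
    xb = np.asarray(gametes_b, dtype=float)
    if xa.shape != xb.shape or xa.ndim != 1:
        raise ValueError("gamete indicator vectors must be 1-D and aligned")
    if xa.size < 2:
        raise ValueError("need at least 2 chromosomes")
    if not (set(np.unique(xa)) <= {0.0, 1.0} and set(np.unique(xb)) <= {0.0, 1.0}):
        raise ValueError("gamete indicators must be 0 or 1")
    p_a = float(xa.mean())
    p_b = float(xb.mean())
    _check_polymorphic(p_a, "A")
    _check_polymorphic(p_b, "B")
    p_ab = float((xa * xb).mean())
    d = p_ab - p_a * p_b
    r = d / np.sqrt(p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDResult(p_A=p_a, p_B=p_b, D=float(d), r=float(r),
                    mode="direct", p_AB=p_ab)


@dataclass(frozen=True)
class LDCompareReport:
    composite: LDResult
    direct: LDResult
    modal_haplotype: str
    modal_frequency: float


def _base_at(hap, site: int) -> str:
    if isinstance(hap, str):
        return hap[site - 1]
    return hap[site]


def ld_compare(cohort: Iterable[tuple], site_a: int, site_b: int,
               allele_a: str | None = None, allele_b: str | None = None,
               denominator: str = "composite") -> LDCompareReport:
    """Composite vs direct LD on the same phased individuals.

    *cohort* is an iterable of haplotype pairs (full sequences or site->base
    maps). The tracked alleles default to the modal base at each site. The
    report also names the most common two-site haplotype and its frequency —
    the headline quantities when comparing genotype-based and directly
    determined haplotype-based estimates.
    """
    pairs = [tuple(p) for p in cohort]
    if not pairs:
        raise ValueError("empty cohort")
    bases_a = [_base_at(h, site_a) for pair in pairs for h in pair]
    bases_b = [_base_at(h, site_b) for pair in pairs for h in pair]
    if allele_a is None:
        allele_a = Counter(bases_a).most_common(1)[0][0]
    if allele_b is None:
        allele_b = Counter(bases_b).most_common(1)[0][0]
    xa = [1 if b == allele_a else 0 for b in bases_a]
    xb = [1 if b == allele_b else 0 for b in bases_b]
    direct = direct_ld(xa, xb)
    counts_a = [xa[2 * i] + xa[2 * i + 1] for i in range(len(pairs))]
    counts_b = [xb[2 * i] + xb[2 * i + 1] for i in range(len(pairs))]
    composite = composite_ld(counts_a, counts_b, denominator)
    two_site = Counter(
        (a, b) for a, b in zip(bases_a, bases_b)
    )
    (ma, mb), m_count = two_site.most_common(1)[0]
    return LDCompareReport(
        composite=composite,
        direct=direct,
        modal_haplotype=f"{ma}{mb}",
        modal_frequency=round(m_count / len(bases_a), 4),
    )
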