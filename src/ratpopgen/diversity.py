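"""Nucleotide diversity statistics per locus, site class and population.

Two per-site estimators of the population mutation parameter theta = 4*N*mu
are computed from each alignment: nucleotide diversity theta_pi (average
pairwise difference per site, with the unbiased k/(k-1) correction per site)
and Watterson's theta_W = S / (a_n * L), a_n = sum_{i=1}^{n-1} 1/i.  Tajima's
D standardizes the difference between the two; negative values indicate an
excess of rare alleles relative to the neutral equilibrium expectation.

Missing data: alleles with >= 20% missing sites at a locus are dropped
before counting (per-locus n), codons touched by N or a gap in any retained
allele are excluded complete-case, and theta_pi uses the per-site number of
non-missing alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from ratpopgen.errors import AggregationError, InsufficientSampleError, MetadataError
from ratpopgen.seq_data import (
    EXCLUDED,
    REPLACEMENT,
    SYNONYMOUS,
    LocusAlignment,
    complete_case_alleles,
    count_site_classes,
)

ALL_SITES = "all"
SITE_CLASSES = (SYNONYMOUS, REPLACEMENT, ALL_SITES)


def harmonic(n: int, power: int = 1) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i**power."""
    return float(sum(1.0 / i**power for i in range(1, n)))


@dataclass
class DiversityStats:
    """Diversity summary for one (locus, population, site class) cell or a
    pooled multilocus row."""

    population_id: str | None
    site_class: str
    n: int
    L: float
    S: int
    theta_pi: float
    theta_w: float
    tajima_d: float | None = None
    k_bar: float = 0.0  # mean pairwise differences, absolute (not per site)
    locus_id: str | None = None
    per_locus_n: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientSampleError(
                f"{self.locus_id or 'pooled'}: n={self.n} < 2"
            )
        assert self.theta_pi >= 0 and self.theta_w >= 0


def theta_w(S: int, n: int, L: float) -> float:
    """Watterson's per-site estimator S / (a_n * L)."""
    if n < 2:
        raise InsufficientSampleError(f"n={n} < 2")
    if L <= 0:
        raise ValueError(f"L={L} must be positive")
    if S < 0:
        raise ValueError(f"S={S} must be non-negative")
    if S == 0:
        return 0.0
    return S / (harmonic(n) * L)


def tajima_constants(n: int) -> dict[str, float]:
    """The a1, a2, b1, b2, c1, c2, e1, e2 constants of Tajima's D."""
    a1 = harmonic(n)
    a2 = harmonic(n, power=2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d(S: int, k_bar: float, n: int) -> float:
    """Tajima's standardized D from S segregating sites and mean pairwise
    differences ``k_bar`` (absolute counts, not per site).

    Undefined for S = 0 (raises ``ValueError``); callers represent that case
    as ``None``, never as zero.
    """
    if n < 2:
        raise InsufficientSampleError(f"n={n} < 2")
    if S < 1:
        raise ValueError("Tajima's D is undefined when S = 0")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:  # n = 2: the normalizing variance vanishes identically
        raise ValueError(f"Tajima's D is undefined for n={n} (zero variance)")
    return (k_bar - S / c["a1"]) / math.sqrt(var)


def _unbiased_het(column: Sequence[str]) -> tuple[float, int]:
    """Per-site contribution to pairwise differences: k/(k-1)*(1 - sum p^2)
    over the k non-missing alleles, and k itself."""
    states = [b for b in column if b not in "N-"]
    k = len(states)
    if k < 2:
        return 0.0, k
    counts: dict[str, int] = {}
    for b in states:
        counts[b] = counts.get(b, 0) + 1
    h = 1.0 - sum((c / k) ** 2 for c in counts.values())
    return h * k / (k - 1), k


def locus_diversity(
    aln: LocusAlignment,
    site_class: str = ALL_SITES,
    population: str | None = None,
) -> DiversityStats:
    """Full per-locus diversity summary for one site class and population."""
    if site_class not in SITE_CLASSES:
        raise ValueError(f"unknown site class {site_class!r}")
    keep = complete_case_alleles(aln, population)
    if len(keep) < 2:
        raise InsufficientSampleError(
            f"locus {aln.locus_id}: {len(keep)} usable alleles for {population or 'all'}"
        )
    sub = LocusAlignment(
        locus_id=aln.locus_id,
        sequences=[aln.sequences[i] for i in keep],
        allele_labels=[aln.allele_labels[i] for i in keep],
        frame_offset=aln.frame_offset,
        outgroup_seq=None,
    )
    counts = count_site_classes(sub)
    if site_class == SYNONYMOUS:
        L = counts.syn_sites
        positions = [
            p for p, c in counts.site_class_by_position.items() if c == SYNONYMOUS
        ]
    elif site_class == REPLACEMENT:
        L = counts.repl_sites
        positions = [
            p for p, c in counts.site_class_by_position.items() if c == REPLACEMENT
        ]
    else:
        L = 3.0 * counts.n_codons_included
        # every variable position inside an included codon, whatever its class
        positions = [
            p
            for p, c in counts.site_class_by_position.items()
            if c in (SYNONYMOUS, REPLACEMENT)
            or counts.exclusion_reasons.get(p) == "multiple_segregating_positions_in_codon"
        ]
    n = len(keep)
    pi_abs = 0.0
    S = 0
    for pos in sorted(positions):
        h, k = _unbiased_het([s[pos] for s in sub.sequences])
        if k >= 2 and h > 0:
            pi_abs += h
            S += 1
    d = tajima_d(S, pi_abs, n) if S >= 1 and n >= 3 else None
    return DiversityStats(
        population_id=population,
        site_class=site_class,
        n=n,
        L=L,
        S=S,
        theta_pi=pi_abs / L if L > 0 else 0.0,
        theta_w=theta_w(S, n, L) if L > 0 else 0.0,
        tajima_d=d,
        k_bar=pi_abs,
        locus_id=aln.locus_id,
    )


def theta_pi(
    aln: LocusAlignment, site_class: str = ALL_SITES, population: str | None = None
) -> float:
    """Per-site nucleotide diversity for one locus/site-class/population."""
    return locus_diversity(aln, site_class, population).theta_pi


def pool_across_loci(stats: Iterable[DiversityStats]) -> DiversityStats:
    """Pool per-locus statistics sharing a population and site class.

    S, L and the pairwise-difference sums add; theta_pi and theta_W are
    site-weighted averages (theta_W pooled = sum(S_i/a_{n_i}) / sum(L_i),
    which reduces to Watterson on summed S and L when all loci share n).
    Tajima's D for the pooled row uses the modal allele count.
    """
    stats = list(stats)
    if not stats:
        raise AggregationError("nothing to pool")
    if len(stats) == 1:
        return replace(stats[0])
    classes = {s.site_class for s in stats}
    pops = {s.population_id for s in stats}
    if len(classes) != 1 or len(pops) != 1:
        raise AggregationError(
            f"cannot pool mixed site classes {classes} or populations {pops}"
        )
    L = sum(s.L for s in stats)
    S = sum(s.S for s in stats)
    pi_abs = sum(s.k_bar for s in stats)
    w_num = sum(s.S / harmonic(s.n) for s in stats)
    ns = [s.n for s in stats]
    n_modal = int(pd.Series(ns).mode().iloc[0])
    d = tajima_d(S, pi_abs, n_modal) if S >= 1 else None
    return DiversityStats(
        population_id=stats[0].population_id,
        site_class=stats[0].site_class,
        n=n_modal,
        L=L,
        S=S,
        theta_pi=pi_abs / L if L > 0 else 0.0,
        theta_w=w_num / L if L > 0 else 0.0,
        tajima_d=d,
        k_bar=pi_abs,
        locus_id=None,
        per_locus_n=tuple(ns),
    )


def _sig2(x: float) -> float:
    """Round to 2 significant figures (report layer only)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + 1)


def diversity_table(
    alignments: Sequence[LocusAlignment],
    populations: Sequence[str] | None = None,
    pooled_label: str = "All",
) -> pd.DataFrame:
    """Per-population + pooled summary table across loci, one column group
    per site class (replacement, synonymous): No. sites (No. variable),
    theta_pi, theta_W, Tajima's D."""
    if populations is None:
        seen: list[str] = []
        for aln in alignments:
            for p in aln.populations:
                if p not in seen:
                    seen.append(p)
        populations = seen
    rows = []
    for pop in list(populations) + [None]:
        row: dict[str, object] = {
            "population": pop if pop is not None else pooled_label
        }
        for sc in (REPLACEMENT, SYNONYMOUS):
            per_locus = []
            for aln in alignments:
                try:
                    per_locus.append(locus_diversity(aln, sc, pop))
                except (InsufficientSampleError, MetadataError):
                    continue  # population absent or < 2 usable alleles at this locus
            if not per_locus:
                continue
            pooled = pool_across_loci(per_locus)
            row[f"{sc}_n_alleles"] = pooled.n
            row[f"{sc}_sites"] = round(pooled.L)
            row[f"{sc}_variable"] = pooled.S
            row[f"{sc}_theta_pi"] = pooled.theta_pi
            row[f"{sc}_theta_w"] = pooled.theta_w
            row[f"{sc}_tajima_d"] = pooled.tajima_d
        rows.append(row)
    return pd.DataFrame(rows)


def format_diversity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Human-readable variant with 2-significant-figure theta values."""
    out = table.copy()
    for col in out.columns:
        if "theta" in col:
            out[col] = out[col].map(lambda x: _sig2(x) if pd.notna(x) else x)
    return out
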