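"""Per-locus neutrality tests.

Three classical checks for departures from the neutral equilibrium model:

* Tajima's D compared against its coalescent null distribution conditioned
  on the observed number of segregating sites (empirical two-tailed p from
  simulated replicates);
* the exact conditional Hardy-Weinberg test on per-site genotype counts;
* the McDonald-Kreitman contrast of replacement vs synonymous variation
  within the species against fixed differences from an outgroup, with the
  neutrality index NI = (Pn/Ps)/(Dn/Ds) and a two-sided Fisher exact p.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from ratpopgen.coalsim import fixed_s_tajima_null
from ratpopgen.diversity import ALL_SITES, locus_diversity
from ratpopgen.errors import InsufficientSampleError, MetadataError
from ratpopgen.seq_data import (
    BASES,
    REPLACEMENT,
    STANDARD_CODE,
    SYNONYMOUS,
    LocusAlignment,
    count_site_classes,
)

logger = logging.getLogger(__name__)


@dataclass
class MKTable:
    """2x2 McDonald-Kreitman contingency table."""

    poly_repl: int
    poly_syn: int
    fix_repl: int
    fix_syn: int

    def __post_init__(self) -> None:
        if min(self.poly_repl, self.poly_syn, self.fix_repl, self.fix_syn) < 0:
            raise ValueError("MK counts must be non-negative")


@dataclass
class MKResult:
    table: MKTable
    neutrality_index: float | None
    p_value: float | None
    status: str  # "ok" or the reason NI / p are undefined


def tajima_d_pvalue(
    observed_d: float,
    n: int,
    S: int,
    n_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Two-tailed empirical p for Tajima's D under the fixed-S coalescent
    null: p = 2 * min over tails of (b + 1)/(n_reps + 1), capped at 1,
    where b counts replicates at least as extreme as the observation."""
    if S < 1:
        raise ValueError("p-value undefined without segregating sites")
    if n_reps < 100:
        raise ValueError("need n_reps >= 100 for a usable null")
    null = fixed_s_tajima_null(n, S, n_reps, seed)
    b_low = int((null <= observed_d).sum())
    b_high = int((null >= observed_d).sum())
    p = 2.0 * (min(b_low, b_high) + 1) / (n_reps + 1)
    return min(1.0, p)


def hwe_exact(genotype_counts: tuple[int, int, int]) -> float:
    """Exact conditional Hardy-Weinberg test for a biallelic site.

    ``genotype_counts`` = (hom_ref, het, hom_alt).  Conditional on the
    allele counts, the null probability of h heterozygotes is

        P(h) = 2**h * N! / (n_aa! * h! * n_bb!) * n_a! * n_b! / (2N)!

    and the p-value sums P over all attainable heterozygote counts (same
    parity as the minor-allele count) whose probability does not exceed the
    observed one.  A monomorphic site returns 1.0 by convention.
    """
    hom_ref, het, hom_alt = genotype_counts
    if min(genotype_counts) < 0 or sum(genotype_counts) < 1:
        raise ValueError("genotype counts must be non-negative with total >= 1")
    n = hom_ref + het + hom_alt
    n_a = 2 * hom_ref + het
    n_b = 2 * hom_alt + het
    if n_a == 0 or n_b == 0:
        return 1.0  # monomorphic: uninformative

    def log_prob(h: int) -> float:
        return (
            h * math.log(2.0)
            + math.lgamma(n + 1)
            - math.lgamma((n_a - h) // 2 + 1)
            - math.lgamma(h + 1)
            - math.lgamma((n_b - h) // 2 + 1)
            + math.lgamma(n_a + 1)
            + math.lgamma(n_b + 1)
            - math.lgamma(2 * n + 1)
        )

    h_min = n_a % 2  # parity fixed by the odd/even minor-allele count
    h_values = range(h_min, min(n_a, n_b) + 1, 2)
    lp_obs = log_prob(het)
    p = 0.0
    for h in h_values:
        lp = log_prob(h)
        if lp <= lp_obs + 1e-12:
            p += math.exp(lp)
    return min(1.0, p)


def mk_test(table: MKTable) -> MKResult:
    """Neutrality index and two-sided Fisher exact p for an MK table.

    NI = (poly_repl/poly_syn) / (fix_repl/fix_syn); any zero among
    poly_syn, fix_repl, fix_syn leaves NI undefined.  The p-value needs both
    the polymorphism and the fixed-difference margins positive.
    """
    ni = None
    status = "ok"
    if table.poly_syn == 0 or table.fix_syn == 0 or table.fix_repl == 0:
        status = "neutrality index undefined (zero denominator margin)"
    else:
        ni = (table.poly_repl / table.poly_syn) / (table.fix_repl / table.fix_syn)
    p = None
    if (table.poly_repl + table.poly_syn) > 0 and (table.fix_repl + table.fix_syn) > 0:
        _, p = fisher_exact(
            [[table.poly_repl, table.poly_syn], [table.fix_repl, table.fix_syn]],
            alternative="two-sided",
        )
        p = float(p)
    elif status == "ok":
        status = "p-value undefined (empty margin)"
    else:
        status += "; p-value undefined (empty margin)"
    return MKResult(table=table, neutrality_index=ni, p_value=p, status=status)


def mk_table_from_alignment(
    aln: LocusAlignment, population: str | None = None
) -> MKTable:
    """Build an MK table for one locus against its outgroup sequence.

    Polymorphic sites take their class from the within-species codon
    classification.  Fixed differences are positions where all ingroup
    alleles share one state and the outgroup another; each is classified by
    the single-base change from the ingroup consensus codon, and codons in
    which a fixed difference co-occurs with another difference (ambiguous
    pathway) are excluded and logged.
    """
    if aln.outgroup_seq is None:
        raise ValueError(f"locus {aln.locus_id}: no outgroup sequence")
    counts = count_site_classes(aln, population)
    poly_syn = counts.n_variable(SYNONYMOUS)
    poly_repl = counts.n_variable(REPLACEMENT)
    seqs = aln.subset(population)
    fix_syn = 0
    fix_repl = 0
    for start in aln.codon_starts():
        codons = {s[start : start + 3] for s in seqs}
        out_codon = aln.outgroup_seq[start : start + 3]
        if any(b not in BASES for c in codons for b in c):
            continue
        if any(b not in BASES for b in out_codon):
            continue
        # positions with a fixed ingroup state differing from the outgroup
        diffs = []
        poly_positions = 0
        for off in range(3):
            states = {c[off] for c in codons}
            if len(states) > 1:
                poly_positions += 1
                continue
            if out_codon[off] not in states:
                diffs.append(off)
        if not diffs:
            continue
        if len(diffs) + poly_positions > 1:
            logger.info(
                "locus %s: codon at %d with %d differences + %d polymorphic "
                "positions excluded from fixed-difference counts",
                aln.locus_id, start, len(diffs), poly_positions,
            )
            continue
        off = diffs[0]
        consensus = next(iter(codons)) if len(codons) == 1 else None
        if consensus is None:  # polymorphic elsewhere handled above
            continue
        mutant = consensus[:off] + out_codon[off] + consensus[off + 1 :]
        if STANDARD_CODE[mutant] == "*" or STANDARD_CODE[consensus] == "*":
            continue
        if STANDARD_CODE[mutant] == STANDARD_CODE[consensus]:
            fix_syn += 1
        else:
            fix_repl += 1
    return MKTable(
        poly_repl=poly_repl, poly_syn=poly_syn, fix_repl=fix_repl, fix_syn=fix_syn
    )


def locus_hwe_pvalues(
    aln: LocusAlignment, population: str | None = None
) -> dict[int, float]:
    """Exact HWE p per biallelic variable site, using individuals with both
    alleles called.  Multiallelic sites are skipped (logged)."""
    idx = aln.indices_for(population)
    by_indiv: dict[str, dict[int, int]] = {}
    for i in idx:
        lab = aln.allele_labels[i]
        by_indiv.setdefault(lab.individual_id, {})[lab.allele_index] = i
    out: dict[int, float] = {}
    for pos in aln.variable_positions(population):
        genos = []
        for alleles in by_indiv.values():
            if len(alleles) != 2:
                continue
            pair = [aln.sequences[i][pos] for i in alleles.values()]
            if any(b in "N-" for b in pair):
                continue
            genos.append(tuple(sorted(pair)))
        states = sorted({b for g in genos for b in g})
        if len(states) < 2:
            continue
        if len(states) > 2:
            logger.info("locus %s: multiallelic site %d skipped in HWE", aln.locus_id, pos)
            continue
        a, b = states
        hom_a = sum(1 for g in genos if g == (a, a))
        het = sum(1 for g in genos if g == (a, b))
        hom_b = sum(1 for g in genos if g == (b, b))
        out[pos] = hwe_exact((hom_a, het, hom_b))
    return out


def neutrality_report(
    alignments: list[LocusAlignment],
    populations: list[str] | None = None,
    site_class: str = ALL_SITES,
    n_reps: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    bh_column: bool = False,
) -> pd.DataFrame:
    """One row per (locus, population): Tajima's D with its fixed-S
    coalescent p, HWE summary, and the MK table when an outgroup exists.

    Raw p-values are reported, matching common practice for per-locus scans;
    ``bh_column=True`` adds a Benjamini-Hochberg adjusted column for the D
    tests as a clearly-labelled extension.
    """
    rng = np.random.default_rng(seed)
    if populations is None:
        populations = sorted({p for a in alignments for p in a.populations})
    rows = []
    for aln in alignments:
        for pop in populations:
            try:
                stats = locus_diversity(aln, site_class, pop)
            except (InsufficientSampleError, MetadataError):
                continue
            d = stats.tajima_d
            p = (
                tajima_d_pvalue(d, stats.n, stats.S, n_reps, rng)
                if d is not None
                else None
            )
            hwe = locus_hwe_pvalues(aln, pop)
            row = {
                "locus_id": aln.locus_id,
                "population": pop,
                "n": stats.n,
                "S": stats.S,
                "tajima_d": d,
                "d_pvalue": p,
                "d_significant": (p is not None and p < alpha),
                "n_hwe_sites": len(hwe),
                "min_hwe_p": min(hwe.values()) if hwe else None,
            }
            if aln.outgroup_seq is not None:
                mk = mk_test(mk_table_from_alignment(aln, pop))
                row.update(
                    mk_poly_repl=mk.table.poly_repl,
                    mk_poly_syn=mk.table.poly_syn,
                    mk_fix_repl=mk.table.fix_repl,
                    mk_fix_syn=mk.table.fix_syn,
                    mk_ni=mk.neutrality_index,
                    mk_p=mk.p_value,
                )
            rows.append(row)
    df = pd.DataFrame(rows)
    if bh_column and len(df) and df["d_pvalue"].notna().any():
        from statsmodels.stats.multitest import multipletests

        mask = df["d_pvalue"].notna()
        adj = pd.Series(np.nan, index=df.index)
        adj[mask] = multipletests(df.loc[mask, "d_pvalue"], method="fdr_bh")[1]
        df["d_pvalue_bh"] = adj
    return df
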