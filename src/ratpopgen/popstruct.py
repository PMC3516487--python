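"""Between-population differentiation and clustering support.

Differentiation is measured with Hudson's sequence-based Fst estimator,
Fst = 1 - Hw/Hb, where Hw is the mean within-population heterozygosity
(unbiased, k/(k-1)-corrected) and Hb the between-population heterozygosity;
multilocus values combine sites by ratio of sums, and the confidence
interval comes from a bootstrap over loci.  Variable sites are further
classified as shared between populations, private to one, or fixed
differences.  Inputs for model-based clustering programs in the de-facto
STRUCTURE text format (two rows per individual, integer alleles, -9 =
missing) can be exported, and the Evanno delta-K statistic picks the number
of clusters from externally produced log-probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ratpopgen.errors import ExportError
from ratpopgen.seq_data import LocusAlignment

logger = logging.getLogger(__name__)

MISSING_CODE = -9
#: integer allele codes for the STRUCTURE export
BASE_CODE = {"A": 1, "C": 2, "G": 3, "T": 4}

SiteCounts = tuple[Mapping[str, int], Mapping[str, int]]  # per-population base counts


@dataclass
class FstResult:
    fst: float
    ci_low: float
    ci_high: float
    n_loci: int
    n_boot: int
    seed: int | None = None
    n_undefined_replicates: int = 0


@dataclass
class SharingTally:
    shared: int = 0
    private_pop1: int = 0
    private_pop2: int = 0
    fixed_diff: int = 0

    @property
    def total(self) -> int:
        return self.shared + self.private_pop1 + self.private_pop2 + self.fixed_diff


def _freqs(counts: Mapping[str, int]) -> tuple[dict[str, float], int]:
    k = sum(counts.values())
    if k == 0:
        return {}, 0
    return {a: c / k for a, c in counts.items()}, k


def _within_het(counts: Mapping[str, int]) -> float | None:
    """Unbiased within-population heterozygosity k/(k-1) * (1 - sum p^2)."""
    p, k = _freqs(counts)
    if k < 2:
        return None
    return (1.0 - sum(v * v for v in p.values())) * k / (k - 1)


def _between_het(c1: Mapping[str, int], c2: Mapping[str, int]) -> float | None:
    p1, k1 = _freqs(c1)
    p2, k2 = _freqs(c2)
    if k1 == 0 or k2 == 0:
        return None
    alleles = set(p1) | set(p2)
    return 1.0 - sum(p1.get(a, 0.0) * p2.get(a, 0.0) for a in alleles)


def hudson_fst(sites: Sequence[SiteCounts]) -> tuple[np.ndarray, float]:
    """Hudson's Fst from per-site allele counts in two populations.

    Returns per-site estimates and the multilocus ratio-of-sums value
    1 - sum(Hw)/sum(Hb).  Sites monomorphic in the pooled sample or with
    fewer than two sampled alleles in either population are excluded (and
    logged).  Negative estimates are returned as computed.
    """
    hw_sum = 0.0
    hb_sum = 0.0
    per_site = []
    n_skipped = 0
    for c1, c2 in sites:
        pooled: dict[str, int] = {}
        for c in (c1, c2):
            for a, v in c.items():
                pooled[a] = pooled.get(a, 0) + v
        if sum(1 for v in pooled.values() if v > 0) < 2:
            n_skipped += 1
            continue
        h1 = _within_het(c1)
        h2 = _within_het(c2)
        hb = _between_het(c1, c2)
        if h1 is None or h2 is None or hb is None:
            n_skipped += 1
            continue
        hw = 0.5 * (h1 + h2)
        hw_sum += hw
        hb_sum += hb
        per_site.append(1.0 - hw / hb if hb > 0 else np.nan)
    if n_skipped:
        logger.info("hudson_fst: %d sites excluded (monomorphic or undersampled)", n_skipped)
    if hb_sum == 0.0:
        raise ValueError("no usable polymorphic sites for Fst")
    return np.asarray(per_site), 1.0 - hw_sum / hb_sum


def locus_site_counts(
    aln: LocusAlignment, pop1: str, pop2: str
) -> list[SiteCounts]:
    """Per-population base counts at every site variable in the pooled
    sample of the two populations."""
    from ratpopgen.errors import MetadataError

    try:
        idx1 = aln.indices_for(pop1)
        idx2 = aln.indices_for(pop2)
    except MetadataError:
        logger.info("locus %s: a population is entirely missing, no Fst sites", aln.locus_id)
        return []
    out: list[SiteCounts] = []
    for pos in range(aln.length):
        counts: list[dict[str, int]] = [{}, {}]
        for which, idx in enumerate((idx1, idx2)):
            for i in idx:
                b = aln.sequences[i][pos]
                if b in "N-":
                    continue
                counts[which][b] = counts[which].get(b, 0) + 1
        pooled = set(counts[0]) | set(counts[1])
        if len(pooled) >= 2:
            out.append((counts[0], counts[1]))
    return out


def dataset_fst(
    alignments: Sequence[LocusAlignment], pop1: str, pop2: str
) -> tuple[float, list[list[SiteCounts]]]:
    """Multilocus Fst across alignments plus the per-locus site data used
    (handy for bootstrapping)."""
    per_locus = [locus_site_counts(aln, pop1, pop2) for aln in alignments]
    all_sites = [s for locus in per_locus for s in locus]
    _, fst = hudson_fst(all_sites)
    return fst, per_locus


def bootstrap_fst(
    per_locus_sites: Sequence[Sequence[SiteCounts]],
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> FstResult:
    """Bootstrap-by-locus percentile CI for the ratio-of-sums Fst.

    Replicates without any usable polymorphic site are excluded from the
    percentiles and counted in ``n_undefined_replicates``.
    """
    if len(per_locus_sites) < 2:
        raise ValueError("bootstrap over loci needs >= 2 loci")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _, point = hudson_fst([s for locus in per_locus_sites for s in locus])
    n_loci = len(per_locus_sites)
    reps = []
    n_undef = 0
    for _ in range(n_boot):
        pick = rng.integers(n_loci, size=n_loci)
        sites = [s for i in pick for s in per_locus_sites[i]]
        try:
            _, f = hudson_fst(sites)
            reps.append(f)
        except ValueError:
            n_undef += 1
    if not reps:
        raise ValueError("all bootstrap replicates were undefined")
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return FstResult(
        fst=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_loci=n_loci,
        n_boot=n_boot,
        seed=seed if isinstance(seed, int) else None,
        n_undefined_replicates=n_undef,
    )


def classify_sharing(site: SiteCounts) -> str | None:
    """Classify one pooled-variable site as ``shared``, ``private_pop1``,
    ``private_pop2`` or ``fixed_diff``; None if one population has no data."""
    c1, c2 = site
    k1 = sum(c1.values())
    k2 = sum(c2.values())
    if k1 == 0 or k2 == 0:
        return None
    poly1 = sum(1 for v in c1.values() if v > 0) >= 2
    poly2 = sum(1 for v in c2.values() if v > 0) >= 2
    if poly1 and poly2:
        return "shared"
    if poly1:
        return "private_pop1"
    if poly2:
        return "private_pop2"
    # both monomorphic: different alleles since the pooled site is variable
    return "fixed_diff"


def tally_sharing(sites: Sequence[SiteCounts]) -> SharingTally:
    tally = SharingTally()
    n_excluded = 0
    for site in sites:
        cls = classify_sharing(site)
        if cls is None:
            n_excluded += 1
            continue
        setattr(tally, cls, getattr(tally, cls) + 1)
    if n_excluded:
        logger.info("tally_sharing: %d sites excluded (all-missing in one population)", n_excluded)
    return tally


def _pooled_minor_count(aln: LocusAlignment, pos: int) -> int:
    counts: dict[str, int] = {}
    for s in aln.sequences:
        b = s[pos]
        if b in "N-":
            continue
        counts[b] = counts.get(b, 0) + 1
    if len(counts) < 2:
        return 0
    return sorted(counts.values())[-2]  # second-largest = minor for biallelic


def _individuals(alignments: Sequence[LocusAlignment]) -> list[tuple[str, str]]:
    """(individual_id, population_id) in order of first appearance."""
    seen: list[tuple[str, str]] = []
    for aln in alignments:
        for lab in aln.allele_labels:
            key = (lab.individual_id, lab.population_id)
            if key not in seen:
                seen.append(key)
    return seen


def export_structure_input(
    alignments: Sequence[LocusAlignment],
    mode: str = "one-snp-per-locus",
    seed: int | np.random.Generator | None = None,
    path: str | Path | None = None,
) -> str:
    """Encode the dataset for model-based clustering (STRUCTURE format).

    Singleton sites (pooled derived-allele count 1) are uninformative and
    removed first.  ``one-snp-per-locus`` then draws one remaining SNP per
    locus uniformly (seeded; loci with no eligible SNP are omitted and
    counted); ``haplotypes-as-alleles`` encodes each distinct remaining
    haplotype at a locus as an integer allele.  Output: one header line of
    locus ids, then two whitespace-separated rows per individual
    (``individual population allele_at_locus_1 ...``), missing data -9.
    """
    if mode not in ("one-snp-per-locus", "haplotypes-as-alleles"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    individuals = _individuals(alignments)
    pop_code = {}
    for _, pop in individuals:
        pop_code.setdefault(pop, len(pop_code) + 1)

    # per locus: mapping (individual, allele_index) -> integer allele code
    locus_cols: list[dict[tuple[str, int], int]] = []
    used_loci: list[str] = []
    n_omitted = 0
    for aln in alignments:
        eligible = [
            p for p in aln.variable_positions() if _pooled_minor_count(aln, p) >= 2
        ]
        if not eligible:
            n_omitted += 1
            continue
        col: dict[tuple[str, int], int] = {}
        if mode == "one-snp-per-locus":
            pos = int(eligible[rng.integers(len(eligible))])
            for s, lab in zip(aln.sequences, aln.allele_labels):
                b = s[pos]
                col[(lab.individual_id, lab.allele_index)] = BASE_CODE.get(b, MISSING_CODE)
        else:
            hap_code: dict[tuple[str, ...], int] = {}
            for s, lab in zip(aln.sequences, aln.allele_labels):
                hap = tuple(s[p] for p in eligible)
                if any(b in "N-" for b in hap):
                    col[(lab.individual_id, lab.allele_index)] = MISSING_CODE
                    continue
                if hap not in hap_code:
                    hap_code[hap] = len(hap_code) + 1
                col[(lab.individual_id, lab.allele_index)] = hap_code[hap]
        locus_cols.append(col)
        used_loci.append(aln.locus_id)
    if not locus_cols:
        raise ExportError("no locus with an informative (non-singleton) polymorphism")
    if n_omitted:
        logger.info("export_structure_input: %d loci omitted (no eligible SNP)", n_omitted)

    lines = ["\t".join(used_loci)]
    for indiv, pop in individuals:
        for allele in (1, 2):
            cells = [indiv, str(pop_code[pop])]
            for col in locus_cols:
                cells.append(str(col.get((indiv, allele), MISSING_CODE)))
            lines.append("\t".join(cells))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def evanno_delta_k(runs: pd.DataFrame) -> pd.DataFrame:
    """Evanno's delta-K from clustering log-probabilities.

    ``runs`` has columns ``K``, ``replicate``, ``log_prob`` with >= 2
    replicates per K over a contiguous K range.  For interior K,
    delta_K = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)) on replicate means; a
    zero standard deviation makes delta-K undefined (NaN, not infinity).
    The returned frame has columns ``K, mean_log_prob, sd_log_prob,
    delta_k, is_best`` with ties on the maximum all flagged.
    """
    required = {"K", "replicate", "log_prob"}
    if not required <= set(runs.columns):
        raise ValueError(f"need columns {sorted(required)}")
    g = runs.groupby("K")["log_prob"]
    means = g.mean()
    sds = g.std(ddof=1)
    ks = sorted(means.index)
    if ks != list(range(min(ks), max(ks) + 1)):
        raise ValueError("K values must be contiguous")
    if (runs.groupby("K")["replicate"].count() < 2).any():
        raise ValueError("need >= 2 replicates per K")
    rows = []
    for k in ks:
        dk = np.nan
        if min(ks) < k < max(ks):
            second_diff = abs(means[k + 1] - 2 * means[k] + means[k - 1])
            dk = second_diff / sds[k] if sds[k] > 0 else np.nan
        rows.append(
            {"K": k, "mean_log_prob": means[k], "sd_log_prob": sds[k], "delta_k": dk}
        )
    out = pd.DataFrame(rows)
    finite = out["delta_k"].dropna()
    if len(finite):
        best = finite.max()
        out["is_best"] = out["delta_k"] == best
    else:
        out["is_best"] = False
    return out
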