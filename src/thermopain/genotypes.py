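"""Genotype encoding, auditing and feature-selection filters.

Genotypes are coded per subject and locus as the number of alleles differing
from the reference sequence (0, 1 or 2); missing calls are masked.  Before a
genotype matrix enters the association stage it passes a fixed filter funnel:

1. Hardy-Weinberg audit: loci whose homozygote/heterozygote composition is
   incompatible with random-mating expectations are removed (an exact
   conditional test; such deviations typically flag genotyping artifacts).
2. Shannon-information filter: near-monomorphic loci carry almost no
   information about any phenotype; the binary carrier entropy of each locus
   is ranked and the most informative set "A" of a computed ABC analysis is
   retained.
3. Effect-size screen: the allele-level chi-square statistic of each locus
   against the phenotype clusters is ranked the same way and set "A" kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abc_analysis import abc_partition

__all__ = [
    "GenotypeMatrix",
    "read_genotype_table",
    "read_vcf",
    "variant_class_summary",
    "hwe_exact_test",
    "hwe_filter",
    "shannon_info",
    "informative_filter",
    "chi2_effect",
    "effect_size_filter",
    "cluster_allele_frequencies",
    "FilterFunnel",
    "preprocess_genotypes",
]

VARIANT_CLASSES = ("SNV", "Del", "Ins", "MIX")

#: LocusInfo columns expected alongside a genotype matrix.
LOCUS_COLUMNS = ("gene", "chrom", "pos", "vclass", "dbsnp", "is_control")


@dataclass
class GenotypeMatrix:
    """Subjects × loci allele-dosage codes with per-locus metadata.

    ``codes`` is a float DataFrame (subjects as rows, locus ids as columns)
    holding values in {0, 1, 2} with NaN for missing calls.  ``info`` is the
    locus metadata table (one row per locus id, columns ``LOCUS_COLUMNS``).
    """

    codes: pd.DataFrame
    info: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.codes.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")
        if list(self.codes.columns) != list(self.info.index):
            raise ValueError("codes columns and locus info index disagree")
        if self.info.index.has_duplicates:
            raise ValueError("locus ids must be unique")

    @property
    def n_subjects(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    @property
    def loci(self) -> pd.Index:
        return self.codes.columns

    def subset_loci(self, loci) -> "GenotypeMatrix":
        loci = list(loci)
        return GenotypeMatrix(self.codes[loci], self.info.loc[loci])

    def genotype_counts(self) -> pd.DataFrame:
        """Per-locus (n0, n1, n2) counts over non-missing subjects."""
        vals = self.codes.to_numpy(dtype=float)
        out = {
            f"n{g}": np.nansum(vals == g, axis=0).astype(int) for g in (0, 1, 2)
        }
        return pd.DataFrame(out, index=self.loci)

    def to_tsv(self, codes_path, info_path) -> None:
        self.codes.to_csv(codes_path, sep="\t", index_label="subject")
        self.info.to_csv(info_path, sep="\t", index_label="locus")


def read_genotype_table(codes_path, info_path) -> GenotypeMatrix:
    """Read a genotype matrix from the tabular (TSV) representation."""
    codes = pd.read_csv(codes_path, sep="\t", index_col="subject")
    info = pd.read_csv(info_path, sep="\t", index_col="locus")
    if "is_control" in info:
        info["is_control"] = info["is_control"].astype(bool)
    return GenotypeMatrix(codes, info)


def _variant_class(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) < len(ref):
        return "Del"
    if len(alt) > len(ref):
        return "Ins"
    return "MIX"


def read_vcf(path) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT field) into 0/1/2 dosage codes.

    Multi-allelic records are split into one locus per alternate allele; the
    code counts copies of that specific allele.  Variant classes are inferred
    from REF/ALT lengths.  ``GENE``, ``DBSNP`` and ``CONTROL`` INFO keys are
    honoured when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    rows: list[dict] = []
    for var in vcf:
        gts = var.genotype.array()  # (n_samples, ploidy+1); last col = phase
        alleles = gts[:, :-1]
        for ai, alt in enumerate(var.ALT, start=1):
            dosage = np.where(
                (alleles < 0).any(axis=1),
                np.nan,
                (alleles == ai).sum(axis=1).astype(float),
            )
            vclass = _variant_class(var.REF, alt)
            locus = f"X{var.CHROM}.{var.POS}.{vclass}"
            if locus in columns:  # distinct alt allele at same site
                locus = f"{locus}.{ai}"
            columns[locus] = dosage
            rows.append(
                {
                    "locus": locus,
                    "gene": var.INFO.get("GENE", ""),
                    "chrom": str(var.CHROM),
                    "pos": var.POS,
                    "vclass": vclass,
                    "dbsnp": var.ID or (var.INFO.get("DBSNP", "") or ""),
                    "is_control": bool(var.INFO.get("CONTROL", 0)),
                }
            )
    if not rows:
        raise ValueError(f"no variant records found in {path}")
    codes = pd.DataFrame(columns, index=pd.Index(subjects, name="subject"))
    info = pd.DataFrame(rows).set_index("locus")
    return GenotypeMatrix(codes, info)


def variant_class_summary(info: pd.DataFrame) -> pd.Series:
    """Percentage of loci per variant class (sums to 100)."""
    if len(info) == 0:
        raise ValueError("empty locus table")
    counts = info["vclass"].value_counts()
    return counts / counts.sum() * 100.0


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n0: int, n1: int, n2: int) -> float:
    """Exact conditional Hardy-Weinberg test for a biallelic locus.

    Conditions on the observed subject count ``n`` and minor-allele count and
    enumerates every feasible heterozygote count (same parity as the minor
    allele count).  Each configuration's conditional probability is

        P(n_het | n, n_minor) ∝ 2^n_het · n! / (n_hom_maj! n_het! n_hom_min!)

    and the p-value sums the probabilities of all configurations no more
    probable than the observed one.  Monomorphic loci return 1.
    """
    for c in (n0, n1, n2):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be non-negative integers")
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("at least one genotyped subject required")
    minor = min(n1 + 2 * n2, n1 + 2 * n0)
    if minor == 0:
        return 1.0

    hets = np.arange(minor % 2, minor + 1, 2)
    hom_minor = (minor - hets) // 2
    hom_major = n - hets - hom_minor
    feasible = hom_major >= 0
    hets, hom_minor, hom_major = hets[feasible], hom_minor[feasible], hom_major[feasible]

    logp = (
        hets * math.log(2.0)
        - _lfact(hom_major)
        - _lfact(hets)
        - _lfact(hom_minor)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[hets == n1][0]
    # 1e-12 relative slack absorbs floating-point ties in the enumeration
    return float(prob[prob <= obs * (1 + 1e-12)].sum())


def _lfact(x):
    from scipy.special import gammaln

    return gammaln(np.asarray(x, dtype=float) + 1.0)


def hwe_filter(matrix: GenotypeMatrix, alpha: float = 0.05):
    """Remove loci whose exact Hardy-Weinberg p-value falls below ``alpha``.

    Returns ``(filtered_matrix, report)`` where the report lists every locus
    with its genotype counts, p-value and keep/remove decision.
    """
    counts = matrix.genotype_counts()
    pvals = np.array(
        [hwe_exact_test(r.n0, r.n1, r.n2) for r in counts.itertuples()]
    )
    report = counts.assign(hwe_p=pvals, removed=pvals < alpha)
    kept = report.index[~report["removed"]]
    return matrix.subset_loci(kept), report


# ---------------------------------------------------------------------------
# Shannon information filter
# ---------------------------------------------------------------------------

def shannon_info(n0: int, n1: int, n2: int, mode: str = "carrier") -> float:
    """Binary Shannon information of a locus, in nats.

    ``Info = −p0·ln p0 − p1·ln p1`` with the 0·ln 0 = 0 convention, where
    ``p1`` is the probability of observing a variant allele in a subject:
    the carrier fraction ``(n1+n2)/n`` (``mode="carrier"``, default) or the
    allele frequency ``(n1+2·n2)/(2n)`` (``mode="allele"``).
    """
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("at least one genotyped subject required")
    if mode == "carrier":
        p1 = (n1 + n2) / n
    elif mode == "allele":
        p1 = (n1 + 2 * n2) / (2 * n)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _binary_entropy(p1)


def _binary_entropy(p1: float) -> float:
    info = 0.0
    for p in (p1, 1.0 - p1):
        if p > 0.0:
            info -= p * math.log(p)
    return info


def locus_shannon_info(matrix: GenotypeMatrix, mode: str = "carrier") -> pd.Series:
    counts = matrix.genotype_counts()
    return pd.Series(
        [shannon_info(r.n0, r.n1, r.n2, mode=mode) for r in counts.itertuples()],
        index=matrix.loci,
        name="shannon_info",
    )


def informative_filter(
    matrix: GenotypeMatrix, mode: str = "carrier", retain: str = "A"
):
    """Keep the loci whose Shannon information falls in ABC set "A".

    The information cutoff is not a fixed constant: it is computed from the
    data by a computed ABC analysis of the per-locus information values.
    ``retain="AB"`` keeps sets A and B instead.  Returns ``(matrix, report)``.
    """
    info = locus_shannon_info(matrix, mode=mode)
    result = abc_partition(info.to_numpy())
    labels = pd.Series(result.set_labels(), index=info.index, name="set")
    keep = labels.isin(set(retain))
    report = pd.DataFrame({"shannon_info": info, "set": labels, "removed": ~keep})
    return matrix.subset_loci(info.index[keep]), report


# ---------------------------------------------------------------------------
# Chi-square effect-size screen
# ---------------------------------------------------------------------------

def _allele_tables(matrix: GenotypeMatrix, labels) -> np.ndarray:
    """Per-locus 2×2 allele-count tables [cluster, ref/variant]."""
    labels = np.asarray(labels)
    if labels.shape[0] != matrix.n_subjects:
        raise ValueError("labels must align with subjects")
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("exactly two phenotype clusters required")
    vals = matrix.codes.to_numpy(dtype=float)
    tables = np.empty((matrix.n_loci, 2, 2))
    for gi, g in enumerate(groups):
        sub = vals[labels == g]
        present = ~np.isnan(sub)
        variant = np.nansum(sub, axis=0)
        total = 2.0 * present.sum(axis=0)
        tables[:, gi, 0] = total - variant
        tables[:, gi, 1] = variant
    return tables


def chi2_effect(matrix: GenotypeMatrix, labels) -> pd.Series:
    """Pearson chi-square of allele counts by cluster, per locus.

    Each subject contributes two alleles; the 2×2 table crosses cluster with
    reference/variant allele.  No continuity correction.  Loci monomorphic in
    the combined sample (or with a degenerate table) score 0.
    """
    tables = _allele_tables(matrix, labels)
    stats = np.zeros(matrix.n_loci)
    for i, tab in enumerate(tables):
        rows = tab.sum(axis=1)
        cols = tab.sum(axis=0)
        total = tab.sum()
        if total == 0 or (cols == 0).any() or (rows == 0).any():
            continue
        expected = np.outer(rows, cols) / total
        stats[i] = ((tab - expected) ** 2 / expected).sum()
    return pd.Series(stats, index=matrix.loci, name="chi2")


def effect_size_filter(matrix: GenotypeMatrix, labels, retain: str = "A"):
    """Keep loci whose cluster-association chi-square falls in ABC set "A"."""
    chi2 = chi2_effect(matrix, labels)
    result = abc_partition(chi2.to_numpy())
    set_labels = pd.Series(result.set_labels(), index=chi2.index, name="set")
    keep = set_labels.isin(set(retain))
    report = pd.DataFrame({"chi2": chi2, "set": set_labels, "removed": ~keep})
    return matrix.subset_loci(chi2.index[keep]), report


def cluster_allele_frequencies(matrix: GenotypeMatrix, labels) -> pd.DataFrame:
    """Variant-allele frequency per locus and cluster, in percent."""
    tables = _allele_tables(matrix, labels)
    groups = np.unique(np.asarray(labels))
    out = {}
    for gi, g in enumerate(groups):
        totals = tables[:, gi].sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[f"freq_cluster_{g}_pct"] = np.where(
                totals > 0, tables[:, gi, 1] / totals * 100.0, 0.0
            )
    return pd.DataFrame(out, index=matrix.loci)


# ---------------------------------------------------------------------------
# Fixed filter funnel
# ---------------------------------------------------------------------------

@dataclass
class FilterFunnel:
    """Locus counts surviving each preprocessing stage, with stage reports."""

    n_input: int
    n_post_hwe: int
    n_post_shannon: int
    n_post_chi2: int
    hwe_report: pd.DataFrame = field(repr=False)
    shannon_report: pd.DataFrame = field(repr=False)
    chi2_report: pd.DataFrame = field(repr=False)

    def summary(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "post_hwe": self.n_post_hwe,
            "post_shannon": self.n_post_shannon,
            "post_chi2": self.n_post_chi2,
        }


def preprocess_genotypes(
    matrix: GenotypeMatrix,
    labels,
    hwe_alpha: float = 0.05,
    shannon_mode: str = "carrier",
    retain: str = "A",
):
    """Run the fixed filter funnel: HWE → Shannon/ABC → chi-square/ABC.

    Returns ``(filtered_matrix, funnel)``; the funnel records the locus count
    surviving each stage together with the per-stage reports.
    """
    m1, hwe_rep = hwe_filter(matrix, alpha=hwe_alpha)
    m2, sh_rep = informative_filter(m1, mode=shannon_mode, retain=retain)
    m3, chi_rep = effect_size_filter(m2, labels, retain=retain)
    funnel = FilterFunnel(
        n_input=matrix.n_loci,
        n_post_hwe=m1.n_loci,
        n_post_shannon=m2.n_loci,
        n_post_chi2=m3.n_loci,
        hwe_report=hwe_rep,
        shannon_report=sh_rep,
        chi2_report=chi_rep,
    )
    return m3, funnel
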