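"""Synthetic cohort generator for thermal-pain genotype-phenotype studies.

No subject-level data are deposited for the study design this package
implements, so every downstream stage is exercised on synthetic cohorts that
reproduce the statistical structure the analysis assumes:

* two phenotype clusters differing mainly in baseline heat/cold pain
  thresholds (z-scored quantitative sensory testing variables);
* a strongly correlated cold-threshold pair (baseline vs. post-UV-B);
* genotype panels mixing Hardy-Weinberg-conforming null loci, rare
  near-monomorphic loci, deliberately HWE-violating loci, cluster-associated
  loci with prescribed per-cluster allele frequencies, and unassociated
  negative-control-gene loci (cytochrome P450 genes).

One master seed drives independent per-component random streams so each
stage is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "CohortSpec",
    "generate_phenotypes",
    "generate_genotypes",
    "generate_cohort",
    "generate_score_sets",
    "write_phenotypes",
    "read_phenotypes",
    "write_vcf",
]

PHENOTYPE_VARS = ("zHPT_baseline", "zHPT_UVB", "zCPT_baseline", "zCPT_UVB")

#: Ion-channel candidate genes (thermosensors) and negative-control genes.
CANDIDATE_GENES = (
    "ASIC1", "ASIC2", "ASIC3", "ASIC4", "TRPA1", "TRPC1", "TRPM2", "TRPM3",
    "TRPM4", "TRPM5", "TRPM8", "TRPV1", "TRPV2", "TRPV3", "TRPV4",
)
CONTROL_GENES = ("CYP2J2", "CYP2C9", "CYP2C19")

_GENE_CHROM = {
    "ASIC1": "12", "ASIC2": "17", "ASIC3": "7", "ASIC4": "2", "TRPA1": "8",
    "TRPC1": "3", "TRPM2": "21", "TRPM3": "9", "TRPM4": "19", "TRPM5": "11",
    "TRPM8": "2", "TRPV1": "17", "TRPV2": "17", "TRPV3": "17", "TRPV4": "12",
    "CYP2J2": "1", "CYP2C9": "10", "CYP2C19": "10",
}

# Class mix mirroring the observed composition of NGS variant calls
_CLASS_PROBS = {"SNV": 0.787, "Del": 0.109, "Ins": 0.086, "MIX": 0.018}

# Between-cluster mean shifts (z-units) sized to reproduce the reported
# cluster contrasts: large on baseline cold, moderate on heat, small on the
# derived UV-B effects.
DEFAULT_EFFECTS = {
    "zHPT_baseline": -1.35,
    "zHPT_UVB": -1.2,
    "zCPT_baseline": -3.0,
    "zCPT_UVB": -2.2,
}

# Cluster-associated allele-frequency pairs (cluster 1, cluster 2) with
# differentials of 0.25-0.35, in the range of the reported selected variants
# (e.g. 0.39 vs 0.66 for the top-ranked regulatory variant).
DEFAULT_ASSOC_FREQS = (
    (0.39, 0.66), (0.15, 0.45), (0.30, 0.60), (0.20, 0.50),
    (0.35, 0.62), (0.25, 0.55), (0.40, 0.68), (0.18, 0.46),
)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic thermal-pain cohort.

    Defaults emulate the genotyped study cohort: 67 subjects in clusters of
    42 and 25, a cold-threshold correlation of 0.812, and an 80-locus panel
    of 8 associated + 60 null + 6 rare + 6 HWE-violating loci, plus 12
    negative-control-gene loci on top.
    """

    cluster_sizes: tuple[int, int] = (42, 25)
    phenotype_effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    cold_correlation: float = 0.812
    heat_correlation: float = 0.55
    uvb_shift_heat: float = 0.8
    uvb_shift_cold: float = 0.2
    n_assoc_loci: int = 8
    n_null_loci: int = 60
    n_rare_loci: int = 6
    n_hwe_violating_loci: int = 6
    n_control_loci: int = 12
    assoc_freqs: tuple = DEFAULT_ASSOC_FREQS
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cluster_sizes) != 2 or any(s < 0 for s in self.cluster_sizes):
            raise ValueError("cluster_sizes must be two non-negative counts")
        for r in (self.cold_correlation, self.heat_correlation):
            if not -1.0 < r < 1.0:
                raise ValueError("correlations must lie in (-1, 1)")
        for f1, f2 in self.assoc_freqs:
            if not (0.0 <= f1 <= 1.0 and 0.0 <= f2 <= 1.0):
                raise ValueError("allele frequencies must lie in [0, 1]")
        for name in ("n_assoc_loci", "n_null_loci", "n_rare_loci",
                     "n_hwe_violating_loci", "n_control_loci"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_assoc_loci > 0 and len(self.assoc_freqs) == 0:
            raise ValueError("assoc_freqs required when n_assoc_loci > 0")

    @property
    def n_subjects(self) -> int:
        return sum(self.cluster_sizes)

    @property
    def n_loci(self) -> int:
        return (self.n_assoc_loci + self.n_null_loci + self.n_rare_loci
                + self.n_hwe_violating_loci + self.n_control_loci)

    @classmethod
    def phenotyping_cohort(cls, **overrides) -> "CohortSpec":
        """The larger phenotyping configuration: 82 subjects, clusters 51/31."""
        overrides.setdefault("cluster_sizes", (51, 31))
        return cls(**overrides)


def _stream(spec: CohortSpec, component: int) -> np.random.Generator:
    # independent, order-insensitive per-component stream off the master seed
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence([int(spec.seed), component])))


def generate_phenotypes(spec: CohortSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw the phenotype table and the planted cluster labels.

    Heat and cold threshold pairs (baseline, post-UV-B) are each drawn from a
    within-cluster bivariate standard normal with the requested correlation;
    the UV-B column adds a constant right-shift toward higher sensitivity.
    Cluster 2 is shifted by ``phenotype_effects``.  Labels (1 or 2) are
    returned for validation only — the analysis never sees them.
    """
    n = spec.n_subjects
    labels = np.repeat([1, 2], spec.cluster_sizes)
    rng = _stream(spec, 0)
    cols = {}
    for prefix, r, shift in (
        ("zHPT", spec.heat_correlation, spec.uvb_shift_heat),
        ("zCPT", spec.cold_correlation, spec.uvb_shift_cold),
    ):
        cov = np.array([[1.0, r], [r, 1.0]])
        draw = rng.multivariate_normal(np.zeros(2), cov, size=n,
                                       method="cholesky")
        cols[f"{prefix}_baseline"] = draw[:, 0]
        cols[f"{prefix}_UVB"] = draw[:, 1] + shift
    table = pd.DataFrame(cols, columns=list(PHENOTYPE_VARS))
    for var, effect in spec.phenotype_effects.items():
        table.loc[labels == 2, var] += effect
    table.insert(0, "sex", rng.permutation(
        np.where(np.arange(n) % 2 == 0, "f", "m")) if n else np.array([], dtype="U1"))
    table.index = pd.Index([f"S{i + 1:03d}" for i in range(n)], name="subject")
    return table, labels


def _locus_metadata(rng: np.random.Generator, gene: str, is_control: bool):
    vclass = rng.choice(list(_CLASS_PROBS), p=list(_CLASS_PROBS.values()))
    chrom = _GENE_CHROM[gene]
    pos = int(rng.integers(1_000_000, 250_000_000))
    return {
        "gene": gene,
        "chrom": chrom,
        "pos": pos,
        "vclass": str(vclass),
        "dbsnp": f"rs{rng.integers(10_000, 99_999_999)}",
        "is_control": is_control,
    }


def generate_genotypes(spec: CohortSpec, labels) -> GenotypeMatrix:
    """Draw the genotype matrix for the planted cluster labels.

    Null and control loci follow Hardy-Weinberg proportions (1-q)^2, 2q(1-q),
    q^2; associated loci use cluster-specific allele frequencies from
    ``assoc_freqs``; rare loci carry at most two heterozygous carriers;
    HWE-violating loci are sampled homozygote-only (maximal heterozygote
    deficit).  Control loci are flagged and named after the control genes.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != spec.n_subjects:
        raise ValueError("labels must have length n_subjects")
    rng = _stream(spec, 1)
    n = spec.n_subjects
    columns: dict[str, np.ndarray] = {}
    rows = []

    def add_locus(codes: np.ndarray, gene: str, is_control: bool, kind: str):
        meta = _locus_metadata(rng, gene, is_control)
        locus = f"X{meta['chrom']}.{meta['pos']}.{meta['vclass']}"
        while locus in columns:
            meta["pos"] += 1
            locus = f"X{meta['chrom']}.{meta['pos']}.{meta['vclass']}"
        columns[locus] = codes.astype(float)
        rows.append({"locus": locus, **meta, "kind": kind})

    genes = list(CANDIDATE_GENES)
    for i in range(spec.n_assoc_loci):
        f1, f2 = spec.assoc_freqs[i % len(spec.assoc_freqs)]
        q = np.where(labels == 1, f1, f2)
        add_locus(rng.binomial(2, q), genes[i % len(genes)], False, "assoc")
    for i in range(spec.n_null_loci):
        q = rng.uniform(0.05, 0.5)
        add_locus(rng.binomial(2, q, size=n), genes[i % len(genes)], False, "null")
    for i in range(spec.n_rare_loci):
        codes = np.zeros(n)
        carriers = rng.choice(n, size=int(rng.integers(1, 3)), replace=False)
        codes[carriers] = 1
        add_locus(codes, genes[i % len(genes)], False, "rare")
    for i in range(spec.n_hwe_violating_loci):
        q = rng.uniform(0.3, 0.5)
        add_locus(2 * rng.binomial(1, q, size=n), genes[i % len(genes)],
                  False, "hwe_violating")
    for i in range(spec.n_control_loci):
        q = rng.uniform(0.05, 0.5)
        add_locus(rng.binomial(2, q, size=n),
                  CONTROL_GENES[i % len(CONTROL_GENES)], True, "control")

    subjects = pd.Index([f"S{i + 1:03d}" for i in range(n)], name="subject")
    codes = pd.DataFrame(columns, index=subjects)
    info = pd.DataFrame(rows).set_index("locus") if rows else pd.DataFrame(
        columns=["gene", "chrom", "pos", "vclass", "dbsnp", "is_control", "kind"]
    ).rename_axis("locus")
    return GenotypeMatrix(codes, info)


def generate_cohort(spec: CohortSpec):
    """Convenience wrapper: phenotypes, labels and genotypes in one call."""
    table, labels = generate_phenotypes(spec)
    matrix = generate_genotypes(spec, labels)
    return table, labels, matrix


def generate_score_sets(means, sds, sizes, seed: int = 0) -> list[np.ndarray]:
    """Normal samples at requested moments (synthetic functional-score sets).

    Stands in for per-variant annotation-score sets (e.g. an analysed set vs.
    positive/negative control sets) whose real values are database lookups.
    """
    means, sds, sizes = map(tuple, (means, sds, sizes))
    if not len(means) == len(sds) == len(sizes):
        raise ValueError("means, sds and sizes must have equal length")
    if any(s <= 0 for s in sds):
        raise ValueError("standard deviations must be positive")
    if any(n < 1 for n in sizes):
        raise ValueError("sizes must be at least 1")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), 2])))
    return [rng.normal(m, s, size=n) for m, s, n in zip(means, sds, sizes)]


# ---------------------------------------------------------------------------
# Writers / readers (round-trip with the genotype module's readers)
# ---------------------------------------------------------------------------

def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index_label="subject")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject")


_CLASS_ALLELES = {
    "SNV": ("A", "G"),
    "Del": ("TAGT", "T"),
    "Ins": ("T", "TC"),
    "MIX": ("AT", "GC"),
}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write the matrix as a minimal single-allele-per-record VCF (GT only).

    REF/ALT strings are chosen per variant class so the class round-trips
    through the VCF reader's length-based inference.
    """
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(matrix.info["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CONTROL,Number=1,Type=Integer,'
                 'Description="Negative-control gene flag">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.codes.index) + "\n")
        for locus, meta in matrix.info.iterrows():
            ref, alt = _CLASS_ALLELES[meta["vclass"]]
            info = f"GENE={meta['gene']};CONTROL={int(bool(meta['is_control']))}"
            gts = "\t".join(
                "./." if np.isnan(v) else gt_map[v]
                for v in matrix.codes[locus].to_numpy(dtype=float)
            )
            fh.write(f"{meta['chrom']}\t{int(meta['pos'])}\t{meta['dbsnp']}\t"
                     f"{ref}\t{alt}\t.\tPASS\t{info}\tGT\t{gts}\n")
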