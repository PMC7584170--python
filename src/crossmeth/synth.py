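"""Synthetic matched blood/sperm methylation cohorts with planted ground truth.

The generator emulates the structures a matched two-tissue methylation-array
study has to cope with, so every downstream stage of the package is testable
without external data:

* a polarised genome-wide beta distribution (more mass below 0.2 and above 0.8
  in sperm than in blood), with CpG-region-dependent baselines (islands mostly
  unmethylated, open sea mostly methylated);
* SNP-driven bi- and trimodal sites whose genotype (Hardy-Weinberg at a
  configurable minor-allele frequency) is shared between both tissues of an
  individual -- the dominant source of genuine cross-tissue covariation;
* a negatively correlated class (genotype effect with opposite sign in the
  two tissues) and an outlier-driven class (one displaced individual);
* imprinted sites at ~50% methylation in blood and ~0% in sperm;
* a planted obesity effect (default +2% methylation in obese men, both
  tissues) at designated sites;
* per-(probe, batch) technical offsets applied identically to both tissues of
  an individual, plus detection-p / bead-count failures for QC to act on.

Noise is additive Gaussian on the proportion scale, clipped to [0, 1], so
planted effects stay interpretable as "% DNA methylation".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .clocks import ClockDefinition, age_transform

__all__ = [
    "SIGNAL_CLASSES",
    "CELL_TYPES",
    "SimConfig",
    "PlantedTruth",
    "Cohort",
    "generate_cohort",
    "generate_reference_profiles",
    "generate_clock",
]

SIGNAL_CLASSES = (
    "null_unimodal",
    "snp_bimodal",
    "snp_trimodal",
    "negative_correlated",
    "outlier_driven",
    "imprinted",
    "obesity_associated",
)

SNP_CLASSES = ("snp_bimodal", "snp_trimodal", "negative_correlated")

CELL_TYPES = ("granulocytes", "cd4t", "cd8t", "b_cells", "nk_cells", "monocytes")

# genotype dosage -> mean beta level, per class
_BIMODAL_LEVELS = np.array([0.15, 0.85, 0.85])
_TRIMODAL_LEVELS = np.array([0.08, 0.50, 0.92])

# P(low / intermediate / high baseline category) per CpG region and tissue;
# sperm is more polarised, islands lean low, open sea leans high.
_CATEGORY_PROBS = {
    "blood": {
        "island": (0.65, 0.25, 0.10),
        "shore": (0.45, 0.35, 0.20),
        "shelf": (0.15, 0.40, 0.45),
        "open_sea": (0.12, 0.38, 0.50),
    },
    "sperm": {
        "island": (0.85, 0.06, 0.09),
        "shore": (0.55, 0.15, 0.30),
        "shelf": (0.18, 0.12, 0.70),
        "open_sea": (0.16, 0.14, 0.70),
    },
}

_CPG_REGIONS = ("island", "shore", "shelf", "open_sea")
_CPG_REGION_PROBS = (0.20, 0.15, 0.05, 0.60)
_GENOMIC_REGIONS = ("tss200", "tss1500", "5utr", "1st_exon", "body", "3utr",
                    "intergenic")
_GENOMIC_REGION_PROBS = (0.05, 0.07, 0.05, 0.04, 0.35, 0.03, 0.41)


def _default_fractions() -> dict[str, float]:
    return {
        "snp_bimodal": 0.010,
        "snp_trimodal": 0.005,
        "negative_correlated": 0.0005,
        "outlier_driven": 0.005,
        "imprinted": 0.002,
        "obesity_associated": 0.001,
    }


@dataclass
class SimConfig:
    """Configuration of a synthetic matched-cohort draw.

    ``class_fractions`` maps non-null signal classes to probe proportions;
    whatever remains is the null (unimodal, uncorrelated) class.  ``n_obese``
    individuals (the last ones) form the obese group; obesity-class probes are
    shifted by ``obesity_effect`` (beta scale) in both their tissues.  When
    ``polarised`` is off, sperm baselines equal blood baselines exactly, giving
    a null cohort with no planted tissue difference.
    """

    n_individuals: int = 47
    n_probes: int = 20_000
    class_fractions: Mapping[str, float] = field(default_factory=_default_fractions)
    maf: float = 0.3
    obesity_effect: float = 0.02
    noise_sd: float = 0.02
    n_obese: int = 0
    batch_assignment: Mapping[str, str] | None = None
    cell_fractions_alpha: tuple[float, ...] = (18.0, 4.5, 2.4, 1.5, 1.5, 2.4)
    polarised: bool = True
    shared_baseline_fraction: float = 0.36
    individual_sd: float = 0.0
    outlier_shift: float = 0.5
    batch_effect_sd: float = 0.005
    detp_failure_rate: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 4:
            raise ValueError("n_individuals must be >= 4 (paired tests undefined)")
        total = 0.0
        for cls, frac in self.class_fractions.items():
            if cls not in SIGNAL_CLASSES or cls == "null_unimodal":
                raise ValueError(f"unknown signal class {cls!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction for {cls!r} outside [0, 1]")
            total += frac
        if total > 1.0 + 1e-12:
            raise ValueError(f"class fractions sum to {total:.3f} > 1")
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError("maf must lie in [0, 1]")
        if self.n_obese > self.n_individuals:
            raise ValueError("n_obese exceeds n_individuals")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def individual_ids(self) -> list[str]:
        return [f"I{i:03d}" for i in range(self.n_individuals)]


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic cohort.

    ``table`` has one row per probe (signal_class, true_effect); ``genotypes``
    holds allele dosages {0,1,2} for SNP-driven probes only (probe x
    individual), shared between both tissues of an individual.
    """

    table: pd.DataFrame
    genotypes: pd.DataFrame | None

    def probes_of(self, signal_class: str) -> pd.Index:
        return self.table.index[self.table["signal_class"] == signal_class]


@dataclass
class Cohort:
    """A generated matched cohort: one matrix column per individual per tissue."""

    blood: pd.DataFrame
    sperm: pd.DataFrame
    detp_blood: pd.DataFrame
    detp_sperm: pd.DataFrame
    beads_blood: pd.DataFrame
    beads_sperm: pd.DataFrame
    samples: pd.DataFrame
    annotation: pd.DataFrame
    truth: PlantedTruth

    def as_tuple(self):
        return (self.blood, self.sperm, self.detp_blood, self.detp_sperm,
                self.beads_blood, self.beads_sperm, self.samples,
                self.annotation, self.truth)


def _assign_classes(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    classes = np.full(config.n_probes, "null_unimodal", dtype=object)
    order = rng.permutation(config.n_probes)
    start = 0
    for cls in SIGNAL_CLASSES[1:]:
        frac = config.class_fractions.get(cls, 0.0)
        count = int(round(frac * config.n_probes))
        classes[order[start:start + count]] = cls
        start += count
    return classes


def _make_annotation(rng: np.random.Generator, probes: list[str],
                     classes: np.ndarray) -> pd.DataFrame:
    n = len(probes)
    chrom_ids = np.array_split(np.arange(n), 22)
    chrom = np.empty(n, dtype=object)
    position = np.empty(n, dtype=int)
    for c, idx in enumerate(chrom_ids, start=1):
        chrom[idx] = f"chr{c}"
        position[idx] = 1 + np.cumsum(rng.integers(500, 5000, size=len(idx)))
    cpg_region = rng.choice(_CPG_REGIONS, size=n, p=_CPG_REGION_PROBS)
    genomic_region = rng.choice(_GENOMIC_REGIONS, size=n, p=_GENOMIC_REGION_PROBS)
    probe_type = rng.choice(["I", "II"], size=n, p=[0.16, 0.84])

    offsets = np.empty(n, dtype=object)
    is_snp = np.isin(classes, SNP_CLASSES)
    for i in range(n):
        if is_snp[i]:
            if rng.random() < 0.8:
                offsets[i] = "0"
            else:
                offsets[i] = str(int(rng.choice([-1, 1, 2, 3, 5, 8, 10])))
        elif rng.random() < 0.05:
            offsets[i] = str(int(rng.integers(11, 46)))
        else:
            offsets[i] = ""

    imprint = np.full(n, "none", dtype=object)
    imp_idx = np.flatnonzero(classes == "imprinted")
    if len(imp_idx):
        imprint[imp_idx] = rng.choice(
            ["known-paternal", "known-maternal", "predicted-paternal",
             "predicted-maternal"],
            size=len(imp_idx), p=[0.5, 0.3, 0.1, 0.1])

    return pd.DataFrame(
        {
            "chrom": chrom,
            "position": position,
            "cpg_region": cpg_region,
            "genomic_region": genomic_region,
            "probe_type": probe_type,
            "snp_offsets": offsets,
            "imprint_class": imprint,
            "on_450k": rng.random(n) < 0.6,
            "signal_class": classes,
        },
        index=pd.Index(probes, name="probe_id"),
    )


def _baseline_for(rng: np.random.Generator, regions: np.ndarray,
                  tissue: str) -> np.ndarray:
    """Region-dependent baseline betas for null probes in one tissue."""
    n = len(regions)
    base = np.empty(n)
    u_cat = rng.random(n)
    low = rng.uniform(0.03, 0.15, n)
    mid = rng.uniform(0.25, 0.75, n)
    high = rng.uniform(0.85, 0.97, n)
    for region in _CPG_REGIONS:
        mask = regions == region
        p_low, p_mid, _ = _CATEGORY_PROBS[tissue][region]
        base[mask] = np.where(
            u_cat[mask] < p_low, low[mask],
            np.where(u_cat[mask] < p_low + p_mid, mid[mask], high[mask]))
    return base


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw a full matched cohort from ``config`` (deterministic in the seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_ind = config.n_individuals
    probes = [f"cg{i:08d}" for i in range(config.n_probes)]
    individuals = config.individual_ids()

    classes = _assign_classes(rng, config)
    annotation = _make_annotation(rng, probes, classes)

    # per-probe baseline means in each tissue
    base_blood = _baseline_for(rng, annotation["cpg_region"].to_numpy(), "blood")
    if config.polarised:
        base_sperm = _baseline_for(rng, annotation["cpg_region"].to_numpy(), "sperm")
        share = rng.random(config.n_probes) < config.shared_baseline_fraction
        base_sperm[share] = base_blood[share]
    else:
        base_sperm = base_blood.copy()

    mean_blood = np.tile(base_blood[:, None], (1, n_ind))
    mean_sperm = np.tile(base_sperm[:, None], (1, n_ind))

    # genotypes under Hardy-Weinberg for SNP-driven classes
    snp_mask = np.isin(classes, SNP_CLASSES)
    genotypes = None
    if snp_mask.any():
        g = rng.binomial(2, config.maf, size=(int(snp_mask.sum()), n_ind))
        genotypes = pd.DataFrame(
            g, index=pd.Index(np.asarray(probes, dtype=object)[snp_mask],
                              name="probe_id"),
            columns=individuals)
        rows = np.flatnonzero(snp_mask)
        cls_rows = classes[rows]
        bi = cls_rows == "snp_bimodal"
        tri = cls_rows == "snp_trimodal"
        neg = cls_rows == "negative_correlated"
        mean_blood[rows[bi]] = _BIMODAL_LEVELS[g[bi]]
        mean_sperm[rows[bi]] = _BIMODAL_LEVELS[g[bi]]
        mean_blood[rows[tri]] = _TRIMODAL_LEVELS[g[tri]]
        mean_sperm[rows[tri]] = _TRIMODAL_LEVELS[g[tri]]
        mean_blood[rows[neg]] = _TRIMODAL_LEVELS[g[neg]]
        mean_sperm[rows[neg]] = _TRIMODAL_LEVELS[::-1][g[neg]]

    # outlier-driven: one displaced individual per probe, both tissues
    out_rows = np.flatnonzero(classes == "outlier_driven")
    true_effect = np.zeros(config.n_probes)
    if len(out_rows):
        base = rng.uniform(0.05, 0.20, size=len(out_rows))
        mean_blood[out_rows] = base[:, None]
        mean_sperm[out_rows] = base[:, None]
        who = rng.integers(0, n_ind, size=len(out_rows))
        mean_blood[out_rows, who] += config.outlier_shift
        mean_sperm[out_rows, who] += config.outlier_shift
        true_effect[out_rows] = config.outlier_shift

    # imprinted: hemi-methylated in blood, erased in sperm
    imp_rows = np.flatnonzero(classes == "imprinted")
    mean_blood[imp_rows] = 0.5
    mean_sperm[imp_rows] = 0.02

    # obesity-associated: cross-tissue shift in the obese group
    obese = np.zeros(n_ind, dtype=bool)
    if config.n_obese:
        obese[-config.n_obese:] = True
    ob_rows = np.flatnonzero(classes == "obesity_associated")
    if len(ob_rows):
        base = rng.uniform(0.3, 0.7, size=len(ob_rows))
        mean_blood[ob_rows] = base[:, None]
        mean_sperm[ob_rows] = base[:, None]
        mean_blood[np.ix_(ob_rows, obese)] += config.obesity_effect
        mean_sperm[np.ix_(ob_rows, obese)] += config.obesity_effect
        true_effect[ob_rows] = config.obesity_effect

    # batch structure: offsets per (probe, batch), identical in both tissues
    if config.batch_assignment is not None:
        batch = np.array([str(config.batch_assignment[i]) for i in individuals],
                         dtype=object)
    else:
        batch = np.array(["b1" if i % 2 == 0 else "b2" for i in range(n_ind)],
                         dtype=object)
    if config.batch_effect_sd > 0:
        levels = pd.unique(batch)
        delta = rng.normal(0.0, config.batch_effect_sd,
                           size=(config.n_probes, len(levels)))
        for j, lev in enumerate(levels):
            cols = batch == lev
            mean_blood[:, cols] += delta[:, [j]]
            mean_sperm[:, cols] += delta[:, [j]]

    # shared per-individual random intercept (systemic inter-individual
    # variation affecting both tissues); off by default
    if config.individual_sd > 0:
        a = rng.normal(0, config.individual_sd, (config.n_probes, n_ind))
        mean_blood = mean_blood + a
        mean_sperm = mean_sperm + a

    if config.noise_sd > 0:
        mean_blood = mean_blood + rng.normal(0, config.noise_sd, mean_blood.shape)
        mean_sperm = mean_sperm + rng.normal(0, config.noise_sd, mean_sperm.shape)
    beta_blood = np.clip(mean_blood, 0.0, 1.0)
    beta_sperm = np.clip(mean_sperm, 0.0, 1.0)

    blood_cols = [f"{i}_blood" for i in individuals]
    sperm_cols = [f"{i}_sperm" for i in individuals]
    idx = pd.Index(probes, name="probe_id")
    blood = pd.DataFrame(beta_blood, index=idx, columns=blood_cols)
    sperm = pd.DataFrame(beta_sperm, index=idx, columns=sperm_cols)

    def _detp(cols):
        p = rng.uniform(0.0, 0.01, size=(config.n_probes, n_ind))
        fail = rng.random((config.n_probes, n_ind)) < config.detp_failure_rate
        p[fail] = rng.uniform(0.06, 0.6, size=int(fail.sum()))
        return pd.DataFrame(p, index=idx, columns=cols)

    def _beads(cols):
        b = rng.integers(8, 26, size=(config.n_probes, n_ind))
        fail = rng.random((config.n_probes, n_ind)) < config.detp_failure_rate
        b[fail] = rng.integers(1, 3, size=int(fail.sum()))
        return pd.DataFrame(b, index=idx, columns=cols)

    detp_blood, detp_sperm = _detp(blood_cols), _detp(sperm_cols)
    beads_blood, beads_sperm = _beads(blood_cols), _beads(sperm_cols)

    # phenotypes
    age = np.clip(rng.normal(35, 5, n_ind), 22, 55).round(1)
    bmi = np.where(
        obese,
        np.clip(rng.normal(30.5, 3.0, n_ind), 26.1, 42.0),
        np.clip(rng.normal(22.5, 1.5, n_ind), 19.0, 25.0),
    ).round(1)
    waist = (2.46 * bmi + rng.normal(0, 4, n_ind)).round(1)
    fasting_insulin = np.exp(rng.normal(np.log(6.0 + 0.4 * (bmi - 22.0)), 0.3))
    homa_ir = fasting_insulin * 5.0 / 22.5
    fractions = rng.dirichlet(config.cell_fractions_alpha, size=n_ind)

    per_ind = pd.DataFrame(
        {
            "individual": individuals,
            "group": np.where(obese, "obese", "lean"),
            "age": age,
            "bmi": bmi,
            "batch": batch,
            "waist": waist,
            "homa_ir": homa_ir.round(3),
            "fasting_insulin": fasting_insulin.round(3),
        }
    )
    for j, ct in enumerate(CELL_TYPES):
        per_ind[f"frac_{ct}"] = fractions[:, j]

    samples = pd.concat(
        [per_ind.assign(tissue="blood", sample_id=blood_cols),
         per_ind.assign(tissue="sperm", sample_id=sperm_cols)],
        ignore_index=True,
    ).set_index("sample_id")

    truth_table = pd.DataFrame(
        {"signal_class": classes, "true_effect": true_effect}, index=idx)
    truth = PlantedTruth(table=truth_table, genotypes=genotypes)

    return Cohort(blood, sperm, detp_blood, detp_sperm, beads_blood,
                  beads_sperm, samples, annotation, truth)


def generate_reference_profiles(
    config: SimConfig,
    n_celltypes: int,
    markers_per_type: int = 50,
    n_background: int = 100,
    max_celltypes: int = 12,
):
    """Cell-type reference profiles plus mixed blood-like betas.

    Each cell type gets a block of marker probes (beta 0.9 in that type, 0.1
    elsewhere); background probes are shared across types.  Mixing fractions
    are Dirichlet draws (``config.cell_fractions_alpha`` when its length
    matches, otherwise flat) and the emitted betas are the convex combination
    of the profiles plus clipped Gaussian noise.

    Returns ``(reference, mixed, fractions)``: probes x cell types,
    probes x individuals, individuals x cell types.
    """
    if n_celltypes < 1:
        raise ValueError("n_celltypes must be >= 1")
    if n_celltypes > max_celltypes:
        raise ValueError(
            f"n_celltypes={n_celltypes} exceeds distinguishable-marker "
            f"capacity ({max_celltypes})")
    rng = np.random.default_rng(config.seed + 1)
    n_probes = markers_per_type * n_celltypes + n_background
    probes = pd.Index([f"ref{i:05d}" for i in range(n_probes)], name="probe_id")
    if n_celltypes <= len(CELL_TYPES):
        names = list(CELL_TYPES[:n_celltypes])
    else:
        names = [f"celltype{j}" for j in range(n_celltypes)]

    ref = np.tile(rng.uniform(0.2, 0.8, n_probes)[:, None], (1, n_celltypes))
    for j in range(n_celltypes):
        block = slice(j * markers_per_type, (j + 1) * markers_per_type)
        ref[block, :] = 0.1
        ref[block, j] = 0.9
    reference = pd.DataFrame(ref, index=probes, columns=names)

    individuals = config.individual_ids()
    if n_celltypes == 1:
        fractions = np.ones((config.n_individuals, 1))
    else:
        alpha = config.cell_fractions_alpha
        if len(alpha) != n_celltypes:
            alpha = np.full(n_celltypes, 2.0)
        fractions = rng.dirichlet(alpha, size=config.n_individuals)
    mixed = ref @ fractions.T
    if config.noise_sd > 0:
        mixed = mixed + rng.normal(0, config.noise_sd, mixed.shape)
    mixed = np.clip(mixed, 0.0, 1.0)
    return (
        reference,
        pd.DataFrame(mixed, index=probes, columns=individuals),
        pd.DataFrame(fractions, index=individuals, columns=names),
    )


def generate_clock(config: SimConfig, ages, n_clock_probes: int = 50,
                   adult_age: float = 20.0):
    """A synthetic epigenetic clock together with betas it exactly inverts.

    Clock probes respond linearly to the log-linear-transformed age; the
    coefficient table is constructed so that at zero noise the emitted clock
    reproduces chronological age exactly on the emitted betas.

    Returns ``(clock, beta)`` with ``beta`` probes x samples.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("empty age vector")
    rng = np.random.default_rng(config.seed + 2)
    probes = pd.Index([f"clk{i:05d}" for i in range(n_clock_probes)],
                      name="probe_id")
    # fixed transform-scale anchors covering roughly ages 7-62
    y0, y1 = -1.0, 2.0
    y = age_transform(ages, adult_age)
    y_norm = (y - y0) / (y1 - y0)

    m = rng.uniform(0.10, 0.40, n_clock_probes)
    s = rng.uniform(0.25, 0.50, n_clock_probes)
    w = rng.uniform(0.5, 1.5, n_clock_probes)
    w = w / w.sum()
    coefs = (y1 - y0) * w / s
    intercept = y0 - float(coefs @ m)

    beta = m[:, None] + s[:, None] * y_norm[None, :]
    if config.noise_sd > 0:
        beta = beta + rng.normal(0, config.noise_sd, beta.shape)
    beta = np.clip(beta, 0.0, 1.0)
    samples = [f"S{i:03d}" for i in range(ages.size)]
    clock = ClockDefinition(
        name="synthetic",
        intercept=intercept,
        coefficients=pd.Series(coefs, index=probes),
        transform="log-linear-age",
        adult_age=adult_age,
    )
    return clock, pd.DataFrame(beta, index=probes, columns=samples)
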