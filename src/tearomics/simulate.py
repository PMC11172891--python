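"""Synthetic tear-proteome and ocular-surface-microbiome data generators.

The proteome generator produces a log2 protein-group intensity matrix for a
two-group cohort with protein-specific within-group variances drawn from a
scaled-inverse-chi-squared prior, a configurable fraction of truly
differential proteins, and intensity-dependent (left-censored, MNAR)
missingness via a logistic detection curve.  The microbiome generator
produces compositional species tables with a group-restricted marker
species.  Both return a :class:`~tearomics.datatypes.SimTruth` so recovery
can be scored against ground truth.

Randomness: one global integer seed per config; every stochastic step uses
a sub-stream derived through :func:`child_rng`, a fixed splitting rule based
on ``numpy.random.SeedSequence`` spawn keys, so outputs are bit-reproducible
and individual steps can be re-run in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import ProteinGroupTable, SampleAnnotation, SimTruth, TaxonAbundanceTable

__all__ = [
    "ProteomeSimConfig",
    "MicrobiomeSimConfig",
    "child_rng",
    "child_seed",
    "simulate_proteome",
    "censor_mnar",
    "simulate_microbiome",
    "DEFAULT_LINEAGES",
]


def _key_ints(keys) -> tuple[int, ...]:
    """Map mixed str/int sub-stream keys to a deterministic integer tuple."""
    out = []
    for k in keys:
        if isinstance(k, str):
            out.append(zlib.crc32(k.encode("utf-8")))
        else:
            out.append(int(k))
    return tuple(out)


def child_rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic sub-stream of the global seed, keyed by (str|int) path."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=_key_ints(keys))
    return np.random.default_rng(ss)


def child_seed(seed: int, *keys) -> int:
    """Integer sub-seed (< 2**31) derived by the same splitting rule."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=_key_ints(keys))
    return int(ss.generate_state(1)[0] % 2**31)


def _check_finite(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"config field {name!r} must be finite, got {value!r}")


@dataclass
class ProteomeSimConfig:
    """Study conditions for the synthetic tear-proteome cohort.

    Defaults emulate a 32-sample glaucoma/control cohort: 16 patients
    (7 female / 9 male) vs 16 controls (10 female / 6 male), ~2250 protein
    groups on the log2 scale, within-protein variances from a
    scaled-inverse-chi-squared(d0_true, s0sq_true) prior, and logistic
    left-censoring that yields roughly a quarter missing values.
    """

    n_proteins: int = 2250
    n_per_group: tuple[int, int] = (16, 16)  # (patients, controls)
    sex_counts: tuple[tuple[int, int], tuple[int, int]] = ((7, 9), (10, 6))  # (F, M) per group
    frac_differential: float = 0.1
    effect_size_sd: float = 1.5  # log2 units
    baseline_mean: float = 25.0  # log2 units
    baseline_sd_between_proteins: float = 2.5
    d0_true: float = 4.0  # prior df of within-protein variances
    s0sq_true: float = 0.09  # prior scale (log2 SD ~ 0.3)
    censor_midpoint: float = 23.0  # log2 intensity of 50% dropout
    censor_slope: float = 0.8  # 1/log2 units
    frac_single_peptide: float = 0.05  # fraction of proteins with 1 peptide
    age_means: tuple[float, float] = (76.5, 68.1)  # (patients, controls), years
    age_sd: float = 7.5
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "frac_differential", "effect_size_sd", "baseline_mean",
            "baseline_sd_between_proteins", "d0_true", "s0sq_true",
            "censor_midpoint", "censor_slope", "frac_single_peptide",
            "age_sd",
        ):
            _check_finite(name, getattr(self, name))
        _check_finite("age_means", self.age_means)
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ValueError("frac_differential must be in [0, 1]")
        if not 0.0 <= self.frac_single_peptide <= 1.0:
            raise ValueError("frac_single_peptide must be in [0, 1]")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if min(self.n_per_group) < 1:
            raise ValueError("n_per_group entries must be >= 1")
        if self.censor_slope <= 0:
            raise ValueError("censor_slope must be > 0")
        if self.d0_true <= 0 or self.s0sq_true <= 0:
            raise ValueError("variance prior parameters must be > 0")
        for g, (nf, nm) in enumerate(self.sex_counts):
            if nf + nm != self.n_per_group[g]:
                raise ValueError(
                    f"sex_counts for group {g} sum to {nf + nm}, "
                    f"expected {self.n_per_group[g]}"
                )


@dataclass
class MicrobiomeSimConfig:
    """Study conditions for the synthetic ocular-surface microbiome.

    ``concentration`` is a Dirichlet concentration: a scalar gives a
    symmetric Dirichlet; ``None`` (default) uses a geometric-decay vector
    (ratio 0.8, total mass 30) so a few species dominate every sample, as in
    real conjunctival profiles.  The marker taxon is present per sample with
    a group-specific prevalence, default (0, 7/16): absent in all patients,
    present in roughly 7 of 16 controls.
    """

    n_taxa: int = 40
    n_per_group: tuple[int, int] = (16, 16)
    concentration: float | np.ndarray | None = None
    marker_taxon_prevalence: tuple[float, float] = (0.0, 7.0 / 16.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 1 or min(self.n_per_group) < 1:
            raise ValueError("counts must be >= 1")
        for p in self.marker_taxon_prevalence:
            _check_finite("marker_taxon_prevalence", p)
            if not 0.0 <= p <= 1.0:
                raise ValueError("marker_taxon_prevalence must be in [0, 1]")
        if self.concentration is not None:
            conc = np.atleast_1d(np.asarray(self.concentration, dtype=float))
            _check_finite("concentration", conc)
            if (conc <= 0).any():
                raise ValueError("concentration must be > 0")
            if conc.size not in (1, self.n_taxa):
                raise ValueError("concentration must be scalar or length n_taxa")

    def concentration_vector(self) -> np.ndarray:
        if self.concentration is None:
            if self.n_taxa == 1:
                return np.array([30.0])
            # geometric decay over ordinary taxa; the marker (last index) gets
            # a fixed share so it stays detectable whenever present
            marker_mass = 0.6
            w = 0.8 ** np.arange(self.n_taxa - 1)
            conc = (30.0 - marker_mass) * w / w.sum()
            return np.append(conc, marker_mass)
        conc = np.atleast_1d(np.asarray(self.concentration, dtype=float))
        if conc.size == 1:
            return np.full(self.n_taxa, float(conc[0]))
        return conc.copy()


def censor_mnar(intensities, midpoint: float, slope: float, seed: int) -> np.ndarray:
    """Left-censoring mask: cell missing with prob 1/(1+exp(slope*(x - m))).

    Lower intensity means higher dropout probability; at ``x == midpoint``
    the probability is exactly 0.5.  Returns a boolean mask (True = missing)
    of the same shape, deterministic given ``seed``.
    """
    if slope <= 0:
        raise ValueError("censor slope must be > 0")
    x = np.asarray(intensities, dtype=float)
    p_missing = expit(slope * (midpoint - x))
    rng = child_rng(seed, "censor")
    return rng.random(x.shape) < p_missing


def _make_annotation(n_per_group, sex_counts, age_means, age_sd, rng) -> SampleAnnotation:
    rows = []
    for g, group in enumerate(("patient", "control")):
        nf, nm = sex_counts[g]
        prefix = "P" if group == "patient" else "C"
        sexes = ["female"] * nf + ["male"] * nm
        ages = rng.normal(age_means[g], age_sd, size=n_per_group[g])
        for i in range(n_per_group[g]):
            rows.append(
                {
                    "sample_id": f"{prefix}{i + 1:02d}",
                    "group": group,
                    "sex": sexes[i],
                    "age": float(np.clip(np.round(ages[i]), 50, 95)),
                }
            )
    table = pd.DataFrame(rows).set_index("sample_id")
    return SampleAnnotation(table)


def simulate_proteome(
    config: ProteomeSimConfig,
) -> tuple[ProteinGroupTable, SampleAnnotation, SimTruth]:
    """Generate a log2 protein-group matrix, sample metadata, and truth.

    Model per protein g and sample s:
    ``x[g, s] = baseline_g + effect_g * 1(s is patient) + eps``,
    ``eps ~ Normal(0, sigma2_g)`` with ``sigma2_g`` from a scaled-inverse-
    chi-squared(d0_true, s0sq_true) prior; effects are Normal(0,
    effect_size_sd^2) on a ``frac_differential`` subset, zero elsewhere.
    Left-censoring is then applied via :func:`censor_mnar`.  Peptide counts
    are >= 1 with a ``frac_single_peptide`` fraction equal to 1 so the
    peptide filter has work to do.
    """
    config.validate()
    seed = config.seed
    n_p, (n1, n2) = config.n_proteins, config.n_per_group
    n = n1 + n2

    ann = _make_annotation(
        config.n_per_group, config.sex_counts, config.age_means, config.age_sd,
        child_rng(seed, "annotation"),
    )
    is_patient = (ann.table["group"] == "patient").to_numpy()

    protein_ids = pd.Index([f"PG{i + 1:05d}" for i in range(n_p)], name="protein_id")

    rng_fx = child_rng(seed, "effects")
    n_diff = int(round(config.frac_differential * n_p))
    diff_idx = rng_fx.choice(n_p, size=n_diff, replace=False)
    is_diff = np.zeros(n_p, dtype=bool)
    is_diff[diff_idx] = True
    effects = np.zeros(n_p)
    effects[is_diff] = rng_fx.normal(0.0, config.effect_size_sd, size=n_diff)

    rng_var = child_rng(seed, "variances")
    # scaled-inverse-chi-squared(d0, s0sq) == d0*s0sq / chi2(d0)
    sigma2 = config.d0_true * config.s0sq_true / rng_var.chisquare(config.d0_true, size=n_p)

    rng_base = child_rng(seed, "baselines")
    baseline = rng_base.normal(
        config.baseline_mean, config.baseline_sd_between_proteins, size=n_p
    )

    rng_noise = child_rng(seed, "noise")
    X = (
        baseline[:, None]
        + effects[:, None] * is_patient[None, :]
        + rng_noise.normal(0.0, 1.0, size=(n_p, n)) * np.sqrt(sigma2)[:, None]
    )

    mask = censor_mnar(X, config.censor_midpoint, config.censor_slope, child_seed(seed, "mnar"))
    intensities = pd.DataFrame(np.where(mask, np.nan, X), index=protein_ids,
                               columns=ann.sample_ids)

    rng_pep = child_rng(seed, "peptides")
    pep = 2 + rng_pep.poisson(6.0, size=n_p)
    single = rng_pep.random(n_p) < config.frac_single_peptide
    pep[single] = 1
    peptide_counts = pd.Series(pep, index=protein_ids, name="peptide_count")

    contaminant = pd.Series(False, index=protein_ids, name="contaminant")

    table = ProteinGroupTable(
        intensities=intensities,
        peptide_counts=peptide_counts,
        contaminant=contaminant,
        scale="log2",
    )
    truth = SimTruth(
        is_differential=pd.Series(is_diff, index=protein_ids),
        true_log2fc=pd.Series(effects, index=protein_ids),
        true_within_variance=pd.Series(sigma2, index=protein_ids),
        censor_params=(config.censor_midpoint, config.censor_slope),
    )
    return table, ann, truth


DEFAULT_LINEAGES: tuple[str, ...] = (
    "k__Bacteria|p__Actinobacteria|g__Cutibacterium|s__Cutibacterium_acnes",
    "k__Bacteria|p__Firmicutes|g__Limosilactobacillus|s__Limosilactobacillus_fermentum",
    "k__Bacteria|p__Firmicutes|g__Staphylococcus|s__Staphylococcus_aureus",
    "k__Bacteria|p__Actinobacteria|g__Corynebacterium|s__Corynebacterium_mastitidis",
)


def _default_taxa(n_taxa: int) -> list[str]:
    """Profiler-style lineage strings: a few named species, the rest filler."""
    phyla = ("Actinobacteria", "Firmicutes", "Proteobacteria", "Bacteroidetes")
    taxa = list(DEFAULT_LINEAGES[:3])
    i = 0
    while len(taxa) < n_taxa - 1:
        ph = phyla[i % len(phyla)]
        taxa.append(f"k__Bacteria|p__{ph}|g__Genus{i + 1}|s__Species_{i + 1}")
        i += 1
    # marker species last so it sits in the low-abundance tail by default
    taxa = taxa[: n_taxa - 1] + [DEFAULT_LINEAGES[3]]
    return taxa[:n_taxa]


def simulate_microbiome(
    config: MicrobiomeSimConfig,
) -> tuple[TaxonAbundanceTable, SampleAnnotation, SimTruth]:
    """Generate compositional species abundances with a marker species.

    Per sample: draw a Dirichlet composition, then decide marker presence by
    a group-specific Bernoulli; if absent, zero the marker and renormalize,
    so compositions always sum to 1 (fraction scale).
    """
    config.validate()
    seed = config.seed
    n1, n2 = config.n_per_group

    ann = _make_annotation(
        config.n_per_group,
        ((0, n1), (0, n2)),  # sexes irrelevant here; all-male placeholder
        (76.5, 68.1), 7.5,
        child_rng(seed, "mb-annotation"),
    )
    taxa = pd.Index(_default_taxa(config.n_taxa), name="lineage")
    marker = taxa[-1]
    conc = config.concentration_vector()

    rng = child_rng(seed, "mb-abundance")
    comp = rng.dirichlet(conc, size=n1 + n2).T  # taxa x samples

    is_patient = (ann.table["group"] == "patient").to_numpy()
    prev = np.where(is_patient, config.marker_taxon_prevalence[0],
                    config.marker_taxon_prevalence[1])
    rng_marker = child_rng(seed, "mb-marker")
    present = rng_marker.random(n1 + n2) < prev

    if config.n_taxa > 1:
        comp[-1, ~present] = 0.0
        comp = comp / comp.sum(axis=0, keepdims=True)
    else:
        # single-taxon composition is identically 1; marker presence moot
        present = np.ones(n1 + n2, dtype=bool)
        comp = np.ones_like(comp)

    abundances = pd.DataFrame(comp, index=taxa, columns=ann.sample_ids)
    table = TaxonAbundanceTable(abundances, unit="fraction")
    truth = SimTruth(
        marker_presence=pd.Series(present, index=ann.sample_ids, name=str(marker)),
    )
    return table, ann, truth
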