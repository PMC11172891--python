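"""Label-free proteomics differential-expression pipeline.

Stages, in order: peptide/contaminant/identification filtering of the
protein-group table, variance-stabilizing renormalization (affine-arsinh
calibration), left-censored downshift imputation, an empirical-Bayes
moderated t test with Benjamini-Hochberg adjustment, a fold-change-dependent
significance curve, and a stability flag over repeated imputation cycles.

The moderated t follows the standard empirical-Bayes treatment: per-protein
residual variances s_g^2 with d degrees of freedom are shrunk toward a prior
(d0, s0^2) estimated from the data by matching the moments of
log s_g^2, giving the posterior variance
``s_tilde^2 = (d0*s0^2 + d*s^2) / (d0 + d)`` and a t statistic on d0 + d
degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import least_squares
from scipy.special import digamma, polygamma

from .datatypes import DEResultTable, ModeratedTestResult, ProteinGroupTable, SampleAnnotation
from .simulate import child_seed
from .stats import bh_adjust

__all__ = [
    "FilterConfig",
    "ImputationConfig",
    "SignificanceCurveConfig",
    "NormalizationModel",
    "filter_protein_groups",
    "fit_vsn",
    "apply_vsn",
    "impute_downshift",
    "fit_moderated_t",
    "significance_threshold",
    "significance_call",
    "stability_flags",
    "run_proteome_pipeline",
    "plot_volcano",
]

LN2 = np.log(2.0)


@dataclass
class FilterConfig:
    """Identification-based protein-group filters.

    ``min_ids_per_group`` applies to each disease group; ``min_ids_female``
    and ``min_ids_male`` apply to the pooled female and male strata.
    """

    min_peptides: int = 2
    min_ids_per_group: int = 8
    min_ids_female: int = 9
    min_ids_male: int = 8

    def validate(self) -> None:
        for name in ("min_peptides", "min_ids_per_group", "min_ids_female", "min_ids_male"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ImputationConfig:
    """Downshifted-Gaussian imputation parameters (per-sample statistics)."""

    width_factor: float = 0.3
    downshift_factor: float = 2.5
    n_cycles: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.width_factor <= 0:
            raise ValueError("width_factor must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


@dataclass
class SignificanceCurveConfig:
    """Fold-change-dependent adjusted-p threshold curve.

    The maximum adjusted p for large fold changes is ``p_max`` and the
    threshold decays to zero as |log2FC| approaches ``lfc_asymptote``; the
    decay rate is ``curve_factor`` times an overall standard deviation
    (of the log2 fold-change vector by default).
    """

    p_max: float = 0.05
    lfc_asymptote: float = 1.0
    curve_factor: float = 0.1
    sd_reference: str = "lfc_sd"  # "lfc_sd" | "intensity_sd"

    def validate(self) -> None:
        if not 0.0 < self.p_max <= 1.0:
            raise ValueError("p_max must be in (0, 1]")
        if self.lfc_asymptote <= 0:
            raise ValueError("lfc_asymptote must be > 0")
        if self.curve_factor < 0:
            raise ValueError("curve_factor must be >= 0")
        if self.sd_reference not in ("lfc_sd", "intensity_sd"):
            raise ValueError("sd_reference must be 'lfc_sd' or 'intensity_sd'")


def filter_protein_groups(
    table: ProteinGroupTable,
    ann: SampleAnnotation,
    cfg: FilterConfig | None = None,
) -> tuple[ProteinGroupTable, dict]:
    """Apply the four identification filters in order; return survivors + log.

    Order: (1) fewer than ``min_peptides`` peptides; (2) contaminants;
    (3) fewer than ``min_ids_per_group`` non-missing values in patients or
    in controls; (4) fewer than ``min_ids_female`` / ``min_ids_male``
    non-missing values among female / male samples.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    missing_ann = set(table.sample_ids) - set(ann.sample_ids)
    if missing_ann:
        raise ValueError(f"annotation missing for samples: {sorted(missing_ann)}")

    strata = {
        "patients": ann.samples_in(group="patient"),
        "controls": ann.samples_in(group="control"),
        "female": ann.samples_in(sex="female"),
        "male": ann.samples_in(sex="male"),
    }
    thresholds = {
        "patients": cfg.min_ids_per_group,
        "controls": cfg.min_ids_per_group,
        "female": cfg.min_ids_female,
        "male": cfg.min_ids_male,
    }
    for name, ids in strata.items():
        ids_in_table = [s for s in ids if s in table.sample_ids]
        if thresholds[name] > len(ids_in_table):
            raise ValueError(
                f"threshold {thresholds[name]} exceeds stratum size "
                f"{len(ids_in_table)} for stratum {name!r}"
            )

    observed = ~table.missing_mask
    alive = pd.Series(True, index=table.protein_ids)
    log: dict[str, int] = {"input": table.n_proteins}

    rule1 = alive & (table.peptide_counts < cfg.min_peptides)
    log["removed_min_peptides"] = int(rule1.sum())
    alive &= ~rule1

    rule2 = alive & table.contaminant.astype(bool)
    log["removed_contaminant"] = int(rule2.sum())
    alive &= ~rule2

    ids_pat = observed[[s for s in strata["patients"] if s in table.sample_ids]].sum(axis=1)
    ids_ctl = observed[[s for s in strata["controls"] if s in table.sample_ids]].sum(axis=1)
    rule3 = alive & ((ids_pat < cfg.min_ids_per_group) | (ids_ctl < cfg.min_ids_per_group))
    log["removed_group_ids"] = int(rule3.sum())
    alive &= ~rule3

    ids_f = observed[[s for s in strata["female"] if s in table.sample_ids]].sum(axis=1)
    ids_m = observed[[s for s in strata["male"] if s in table.sample_ids]].sum(axis=1)
    rule4 = alive & ((ids_f < cfg.min_ids_female) | (ids_m < cfg.min_ids_male))
    log["removed_sex_ids"] = int(rule4.sum())
    alive &= ~rule4

    log["surviving"] = int(alive.sum())
    return table.subset(table.protein_ids[alive]), log


@dataclass
class NormalizationModel:
    """Per-sample affine-arsinh calibration h_s(x) = arsinh(a_s + b_s x)/ln 2."""

    a: pd.Series
    b: pd.Series
    reference: pd.Series = field(repr=False, default=None)
    converged: bool = True
    n_iter: int = 0

    def transform_sample(self, x: np.ndarray, sample_id) -> np.ndarray:
        return np.arcsinh(self.a[sample_id] + self.b[sample_id] * x) / LN2


def _trimmed_fit(x: np.ndarray, ref: np.ndarray, a0: float, b0: float,
                 trim: float) -> tuple[float, float]:
    """Fit (a, b>0) minimizing trimmed squared residuals of arsinh(a+bx)/ln2 - ref."""

    def resid(theta, xs, rs):
        return np.arcsinh(theta[0] + np.exp(theta[1]) * xs) / LN2 - rs

    theta = np.array([a0, np.log(b0)])
    sol = least_squares(resid, theta, args=(x, ref), method="lm")
    r = np.abs(resid(sol.x, x, ref))
    n_keep = max(2, int(np.ceil(len(x) * (1.0 - trim))))
    keep = np.argsort(r)[:n_keep]
    sol = least_squares(resid, sol.x, args=(x[keep], ref[keep]), method="lm")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def fit_vsn(
    table: ProteinGroupTable,
    trim: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> NormalizationModel:
    """Fit variance-stabilizing calibration on a raw-scale table.

    Alternates between (i) a reference profile (per-protein median of
    transformed values over complete cases) and (ii) per-sample trimmed
    least-squares fits of (a_s, b_s) to that reference, until the relative
    parameter change falls below ``tol`` or ``max_iter`` iterations; a
    warning is issued on non-convergence and the best iterate returned.
    """
    if table.scale != "raw":
        raise ValueError("fit_vsn expects a raw-scale table")
    X = table.intensities
    if (X.stack() < 0).any():
        raise ValueError("negative raw intensities")
    if table.n_samples < 2:
        raise ValueError("need >= 2 samples to normalize")
    complete = X.dropna(axis=0)
    if complete.shape[0] < 10:
        raise ValueError("too few complete-case proteins to fit normalization")

    samples = X.columns
    # init: pure-scale calibration placing median intensity in the log regime
    med = complete.median(axis=0)
    b = (1.0 / med).to_dict()
    a = {s: 0.0 for s in samples}

    Xc = complete.to_numpy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        transformed = np.column_stack(
            [np.arcsinh(a[s] + b[s] * Xc[:, j]) / LN2 for j, s in enumerate(samples)]
        )
        ref = np.median(transformed, axis=1)
        max_rel = 0.0
        for j, s in enumerate(samples):
            a_new, b_new = _trimmed_fit(Xc[:, j], ref, a[s], b[s], trim)
            rel = max(
                abs(a_new - a[s]) / (abs(a[s]) + 1e-12),
                abs(b_new - b[s]) / (abs(b[s]) + 1e-12),
            )
            max_rel = max(max_rel, rel)
            a[s], b[s] = a_new, b_new
        if max_rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"vsn calibration did not converge in {max_iter} iterations")

    transformed = np.column_stack(
        [np.arcsinh(a[s] + b[s] * Xc[:, j]) / LN2 for j, s in enumerate(samples)]
    )
    return NormalizationModel(
        a=pd.Series(a), b=pd.Series(b),
        reference=pd.Series(np.median(transformed, axis=1), index=complete.index),
        converged=converged, n_iter=it,
    )


def apply_vsn(model: NormalizationModel, table: ProteinGroupTable) -> ProteinGroupTable:
    """Apply a fitted calibration; output is flagged log2 scale, NaN preserved."""
    if table.scale != "raw":
        raise ValueError("apply_vsn expects a raw-scale table")
    out = table.intensities.copy()
    for s in out.columns:
        out[s] = np.arcsinh(model.a[s] + model.b[s] * out[s].to_numpy()) / LN2
    return ProteinGroupTable(
        intensities=out,
        peptide_counts=table.peptide_counts.copy(),
        contaminant=table.contaminant.copy(),
        scale="log2",
    )


def impute_downshift(
    table: ProteinGroupTable,
    cfg: ImputationConfig | None = None,
    cycle_seed: int = 0,
) -> pd.DataFrame:
    """Replace missing log2 intensities with downshifted-Gaussian draws.

    Per sample s with observed mean mu_s and SD sigma_s, each missing cell
    draws from Normal(mu_s - downshift_factor*sigma_s,
    (width_factor*sigma_s)^2).  Observed cells are never touched.
    """
    cfg = cfg or ImputationConfig()
    cfg.validate()
    if table.scale != "log2":
        raise ValueError("impute_downshift expects a log2-scale table")
    X = table.intensities.to_numpy(copy=True)
    rng = np.random.default_rng(cycle_seed)
    for j, s in enumerate(table.sample_ids):
        col = X[:, j]
        obs = col[~np.isnan(col)]
        if len(obs) < 2:
            raise ValueError(f"sample {s!r} has fewer than 2 observed values")
        mu, sigma = obs.mean(), obs.std(ddof=1)
        miss = np.isnan(col)
        if miss.any():
            col[miss] = rng.normal(
                mu - cfg.downshift_factor * sigma,
                cfg.width_factor * sigma,
                size=int(miss.sum()),
            )
    return pd.DataFrame(X, index=table.protein_ids, columns=table.sample_ids)


def _trigamma_inverse(y: float) -> float:
    """Solve polygamma(1, x) = y for x > 0 (Newton, as in standard EB fits)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_moderated_t(
    X: pd.DataFrame,
    ann: SampleAnnotation,
    d0_override: float | None = None,
    s0sq_override: float | None = None,
) -> ModeratedTestResult:
    """Empirical-Bayes moderated two-group t test on a complete log2 matrix.

    log2FC = mean(patients) - mean(controls); residual variance s^2 with
    d = n1 + n2 - 2 df.  The prior (d0, s0^2) is estimated by matching
    moments of e = ln s^2 - psi(d/2) + ln(d/2): solve
    psi'(d0/2) = var(e) - psi'(d/2) (d0 = inf when the RHS <= 0) and
    s0^2 = exp(mean(e) + psi(d0/2) - ln(d0/2)).  Posterior variance
    s_tilde^2 = (d0 s0^2 + d s^2)/(d0 + d); t on d0 + d df; BH-adjusted
    p-values included.  ``d0_override=0`` recovers the ordinary pooled t.
    """
    pat = [s for s in X.columns if s in ann.samples_in(group="patient")]
    ctl = [s for s in X.columns if s in ann.samples_in(group="control")]
    n1, n2 = len(pat), len(ctl)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    if X.isna().to_numpy().any():
        raise ValueError("matrix must be complete (impute first)")

    xp = X[pat].to_numpy()
    xc = X[ctl].to_numpy()
    d = n1 + n2 - 2
    log2fc = xp.mean(axis=1) - xc.mean(axis=1)
    ss = ((xp - xp.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xc - xc.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d

    pos = s2 > 0
    if not pos.any():
        raise ValueError("zero residual variance everywhere; degenerate input")

    if d0_override is not None:
        d0 = float(d0_override)
        if s0sq_override is None and d0 > 0:
            raise ValueError("s0sq_override required when forcing d0 > 0")
        s0sq = float(s0sq_override) if s0sq_override is not None else 0.0
    else:
        e = np.log(s2[pos]) - digamma(d / 2.0) + np.log(d / 2.0)
        rhs = np.var(e, ddof=1) - polygamma(1, d / 2.0)
        if rhs <= 0:
            d0 = np.inf
            s0sq = float(np.exp(e.mean()))
        else:
            d0 = 2.0 * _trigamma_inverse(float(rhs))
            s0sq = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0sq + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / se, 0.0)
    if np.isinf(df_total):
        p_raw = 2.0 * sps.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * sps.t.sf(np.abs(t_mod), df_total)
    p_adj = bh_adjust(p_raw)

    tbl = pd.DataFrame(
        {
            "log2fc": log2fc,
            "s2": s2,
            "t_mod": t_mod,
            "df_total": df_total,
            "p_raw": p_raw,
            "p_adj": p_adj,
        },
        index=X.index,
    )
    return ModeratedTestResult(table=tbl, d0_hat=float(d0), s0sq_hat=float(s0sq),
                               n1=n1, n2=n2)


def significance_threshold(
    abs_lfc, cfg: SignificanceCurveConfig, sigma: float
) -> np.ndarray:
    """Adjusted-p threshold tau(l): 0 at/below the fold-change asymptote,
    rising as p_max * exp(-c / (l - asymptote)) with c = curve_factor * sigma."""
    l = np.asarray(abs_lfc, dtype=float)
    c = cfg.curve_factor * sigma
    with np.errstate(divide="ignore", over="ignore"):
        tau = np.where(
            l > cfg.lfc_asymptote,
            cfg.p_max * np.exp(-c / np.maximum(l - cfg.lfc_asymptote, 1e-300)),
            0.0,
        )
    return tau


def significance_call(
    res: ModeratedTestResult,
    cfg: SignificanceCurveConfig | None = None,
    intensities: pd.DataFrame | None = None,
) -> pd.Series:
    """Flag proteins whose adjusted p falls under the fold-change curve.

    A protein is significant iff |log2FC| exceeds the asymptote and
    p_adj <= tau(|log2FC|); the reference SD is that of the log2FC vector
    (default) or of all intensities (``sd_reference='intensity_sd'``, which
    requires ``intensities``).
    """
    cfg = cfg or SignificanceCurveConfig()
    cfg.validate()
    lfc = res.table["log2fc"].to_numpy()
    if cfg.sd_reference == "lfc_sd":
        sigma = float(np.std(lfc, ddof=1))
    else:
        if intensities is None:
            raise ValueError("sd_reference='intensity_sd' requires the intensity matrix")
        sigma = float(np.std(intensities.to_numpy().ravel(), ddof=1))
    tau = significance_threshold(np.abs(lfc), cfg, sigma)
    sig = (np.abs(lfc) > cfg.lfc_asymptote) & (res.table["p_adj"].to_numpy() <= tau)
    return pd.Series(sig, index=res.table.index, name="significant")


def stability_flags(
    table: ProteinGroupTable,
    ann: SampleAnnotation,
    icfg: ImputationConfig | None = None,
    scfg: SignificanceCurveConfig | None = None,
) -> DEResultTable:
    """Run impute -> moderated t -> BH -> curve over ``n_cycles`` seeds.

    The headline ``significant`` column comes from cycle 1 (the reference
    cycle); ``stable`` marks proteins significant in every cycle.  Per-cycle
    calls are retained in ``cycle_calls`` for diagnostics.
    """
    icfg = icfg or ImputationConfig()
    scfg = scfg or SignificanceCurveConfig()
    icfg.validate()
    scfg.validate()

    calls = {}
    ref_res: ModeratedTestResult | None = None
    for cycle in range(1, icfg.n_cycles + 1):
        seed_c = child_seed(icfg.seed, "impute-cycle", cycle)
        Xc = impute_downshift(table, icfg, cycle_seed=seed_c)
        res = fit_moderated_t(Xc, ann)
        calls[cycle] = significance_call(res, scfg, intensities=Xc)
        if cycle == 1:
            ref_res = res

    cycle_calls = pd.DataFrame(calls)
    significant = cycle_calls[1]
    stable = cycle_calls.all(axis=1)

    tbl = ref_res.table.copy()
    tbl["significant"] = significant
    tbl["stable"] = stable
    return DEResultTable(
        table=tbl,
        d0_hat=ref_res.d0_hat,
        s0sq_hat=ref_res.s0sq_hat,
        cycle_calls=cycle_calls,
        params={
            "imputation": {
                "width_factor": icfg.width_factor,
                "downshift_factor": icfg.downshift_factor,
                "n_cycles": icfg.n_cycles,
                "seed": icfg.seed,
                "cycle_seeds": [child_seed(icfg.seed, "impute-cycle", c)
                                for c in range(1, icfg.n_cycles + 1)],
            },
            "significance_curve": {
                "p_max": scfg.p_max,
                "lfc_asymptote": scfg.lfc_asymptote,
                "curve_factor": scfg.curve_factor,
                "sd_reference": scfg.sd_reference,
            },
        },
    )


def run_proteome_pipeline(
    table: ProteinGroupTable,
    ann: SampleAnnotation,
    filter_cfg: FilterConfig | None = None,
    imputation_cfg: ImputationConfig | None = None,
    curve_cfg: SignificanceCurveConfig | None = None,
) -> tuple[DEResultTable, dict]:
    """Full differential-expression run: filter -> normalize -> impute/test.

    Raw-scale input is renormalized by the variance-stabilizing calibration;
    log2-scale input proceeds directly.  Returns the volcano-ready result
    table and a run report (filter counts, parameters, seeds, prior).
    """
    filter_cfg = filter_cfg or FilterConfig()
    filtered, filter_log = filter_protein_groups(table, ann, filter_cfg)

    normalized = False
    if filtered.scale == "raw":
        model = fit_vsn(filtered)
        filtered = apply_vsn(model, filtered)
        normalized = True

    de = stability_flags(filtered, ann, imputation_cfg, curve_cfg)

    report = {
        "n_input_proteins": table.n_proteins,
        "filter": filter_log,
        "vsn_applied": normalized,
        "d0_hat": de.d0_hat,
        "s0sq_hat": de.s0sq_hat,
        "n_significant": de.n_significant,
        "n_stable": de.n_stable,
        **de.params,
    }
    return de, report


def plot_volcano(de: DEResultTable, path, cfg: SignificanceCurveConfig | None = None):
    """Write a volcano plot (log2FC vs -log10 adjusted p) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tbl = de.table
    with np.errstate(divide="ignore"):
        y = -np.log10(np.maximum(tbl["p_adj"].to_numpy(), 1e-300))
    colors = np.where(tbl["stable"], "crimson",
                      np.where(tbl["significant"], "orange", "grey"))
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(tbl["log2fc"], y, s=8, c=colors, alpha=0.6, linewidths=0)
    ax.set_xlabel("log2 fold change (patient - control)")
    ax.set_ylabel("-log10 adjusted p")
    ax.axvline(1, ls="--", c="k", lw=0.7)
    ax.axvline(-1, ls="--", c="k", lw=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
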