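"""Criterion-validation statistics for device comparisons.

Given per-participant criterion PAEE (chamber or DLW) and the values
reported by each device, this module computes the full agreement suite:

* Dunnett many-to-one comparisons of every device against the criterion
  (family-wise adjusted, two-sided), with the adjusted p-values obtained
  from the equicoordinate distribution of correlated t variates by
  seeded Monte Carlo;
* mean absolute percentage error (MAPE) with its SD;
* Pearson and Spearman correlations, and the partial correlation
  controlling for body weight;
* the modified Bland-Altman analysis: bias, 1.96-SD limits of agreement,
  and the proportional-bias correlation of the criterion with the
  device-criterion differences (the criterion, not the pair mean, on the
  x-axis).

``DeviceValidation`` assembles these per device and measure into a
results object with a printable summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def mape(device, criterion) -> tuple[float, float]:
    """Mean and SD of per-subject absolute percentage error vs criterion."""
    d = np.asarray(device, dtype=float)
    c = np.asarray(criterion, dtype=float)
    if d.shape != c.shape:
        raise ValueError("vectors must have equal length")
    zero = np.nonzero(c == 0)[0]
    if zero.size:
        raise ValueError(f"criterion is zero for subject index {zero[0]}")
    ape = 100.0 * np.abs(d - c) / np.abs(c)
    return float(np.mean(ape)), float(np.std(ape, ddof=1)) if ape.size > 1 else 0.0


def correlations(x, y) -> tuple[float, float, float, float]:
    """(Pearson r, p) and (Spearman rho, p), t-approximation p-values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3 for correlations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    pr = stats.pearsonr(x, y)
    sp = stats.spearmanr(x, y)
    return float(pr.statistic), float(pr.pvalue), float(sp.statistic), float(sp.pvalue)


def partial_correlation(x, y, z) -> tuple[float, float]:
    """Pearson correlation of x and y after removing a linear z effect.

    Computed as the correlation of OLS residuals of x|z and y|z; the
    p-value uses a t distribution with n - 3 degrees of freedom.  When a
    variable is collinear with z the residuals vanish and the partial
    correlation is reported as 0 with p = 1 (degenerate case).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 for a partial correlation")
    zmat = np.column_stack([np.ones(n), z])
    rx = x - zmat @ np.linalg.lstsq(zmat, x, rcond=None)[0]
    ry = y - zmat @ np.linalg.lstsq(zmat, y, rcond=None)[0]
    sx, sy = np.std(rx), np.std(ry)
    if sx < 1e-12 * max(1.0, float(np.std(x))) or sy < 1e-12 * max(1.0, float(np.std(y))):
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def bland_altman_modified(
    criterion, device
) -> tuple[float, tuple[float, float], float, float]:
    """Modified Bland-Altman: bias, limits of agreement, proportional bias.

    Differences are device - criterion; bias is their mean and the
    limits of agreement bias +/- 1.96 SD.  Proportional bias is the
    Pearson correlation of the *criterion* with the differences,
    following the modification that plots the criterion on the x-axis.
    """
    c = np.asarray(criterion, dtype=float)
    d = np.asarray(device, dtype=float)
    if len(c) < 3:
        raise ValueError("need n >= 3")
    diff = d - c
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    scale = max(1.0, float(np.max(np.abs(c))), float(np.max(np.abs(d))))
    if sd <= 1e-10 * scale:
        # constant offset (to rounding): no proportional bias by definition
        return bias, loa, 0.0, 1.0
    pr = stats.pearsonr(c, diff)
    return bias, loa, float(pr.statistic), float(pr.pvalue)


# ---------------------------------------------------------------------------
# Dunnett many-to-one
# ---------------------------------------------------------------------------

@dataclass
class DunnettResult:
    """Dunnett comparison of k treatment groups against one control."""

    t_stats: np.ndarray
    p_adjusted: np.ndarray
    critical_value: float
    df: int
    alpha: float
    mc_draws: int


def _max_abs_t_draws(
    lambdas: np.ndarray, df: int, mc_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo draws of max_i |T_i| for correlated t variates.

    The Dunnett statistics share the control mean, giving correlation
    lambda_i * lambda_j with lambda_i = sqrt(n_i / (n_i + n0)) (0.5 in
    the balanced case); all share one pooled-variance chi-square.
    """
    k = len(lambdas)
    z0 = rng.standard_normal(mc_draws)
    e = rng.standard_normal((mc_draws, k))
    z = lambdas * z0[:, None] + np.sqrt(1.0 - lambdas**2) * e
    s = np.sqrt(rng.chisquare(df, mc_draws) / df)
    return np.max(np.abs(z), axis=1) / s


def dunnett_many_to_one(
    control,
    treatments,
    alpha: float = 0.05,
    mc_draws: int = 100_000,
    seed: int | None = None,
) -> DunnettResult:
    """Two-sided Dunnett test of each treatment group against a control.

    ``treatments`` is a k x n matrix (rows are groups) or a list of
    1-D arrays (groups may be unbalanced).  Pooled-variance t statistics
    are referred to the equicoordinate distribution of k correlated t
    variates, evaluated by seeded Monte Carlo with ``mc_draws`` draws.
    """
    c = np.asarray(control, dtype=float)
    groups = [np.asarray(g, dtype=float) for g in treatments]
    if len(groups) < 1:
        raise ValueError("need at least one treatment group")
    if len(c) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")

    n0 = len(c)
    ns = np.array([len(g) for g in groups])
    df = int(n0 + ns.sum() - (len(groups) + 1))
    ss = np.sum((c - c.mean()) ** 2) + sum(np.sum((g - g.mean()) ** 2) for g in groups)
    if ss <= 0:
        raise ValueError("zero within-group variance: Dunnett t undefined")
    s2 = ss / df
    means = np.array([g.mean() for g in groups])
    t_stats = (means - c.mean()) / np.sqrt(s2 * (1.0 / ns + 1.0 / n0))

    rng = np.random.default_rng(seed)
    lambdas = np.sqrt(ns / (ns + n0))
    max_abs = _max_abs_t_draws(lambdas, df, mc_draws, rng)
    p_adj = np.array([np.mean(max_abs >= abs(t)) for t in t_stats])
    crit = float(np.quantile(max_abs, 1.0 - alpha))
    return DunnettResult(
        t_stats=t_stats,
        p_adjusted=p_adj,
        critical_value=crit,
        df=df,
        alpha=alpha,
        mc_draws=mc_draws,
    )


def dunnett_critical_value(
    k: int,
    n_per_group: int,
    n_control: int | None = None,
    alpha: float = 0.05,
    mc_draws: int = 200_000,
    seed: int | None = None,
) -> float:
    """Two-sided Dunnett critical value |t| for k balanced comparisons."""
    n0 = n_per_group if n_control is None else n_control
    df = n0 + k * n_per_group - (k + 1)
    lambdas = np.full(k, np.sqrt(n_per_group / (n_per_group + n0)))
    rng = np.random.default_rng(seed)
    max_abs = _max_abs_t_draws(lambdas, df, mc_draws, rng)
    return float(np.quantile(max_abs, 1.0 - alpha))


def dunnett_paired(
    control,
    treatments,
    alpha: float = 0.05,
    mc_draws: int = 100_000,
    seed: int | None = None,
) -> DunnettResult:
    """Repeated-measures variant: max-|t| over within-subject differences.

    Each treatment is measured on the same subjects as the control.  Per
    device, a one-sample t on the paired differences; the family-wise
    adjustment draws from a multivariate t with the empirical correlation
    of the difference vectors and n - 1 degrees of freedom.
    """
    c = np.asarray(control, dtype=float)
    tr = np.asarray(treatments, dtype=float)
    if tr.ndim == 1:
        tr = tr[None, :]
    k, n = tr.shape
    if n != len(c) or n < 3:
        raise ValueError("paired variant needs matching subjects, n >= 3")
    diffs = tr - c
    sds = diffs.std(axis=1, ddof=1)
    means = diffs.mean(axis=1)
    # devices identical to the criterion have zero-variance differences;
    # their paired t is 0 (no shift) rather than undefined
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stats = np.where(
            sds > 0,
            means / np.where(sds > 0, sds, 1.0) * np.sqrt(n),
            np.where(means == 0, 0.0, np.sign(means) * np.inf),
        )
    df = n - 1

    if k > 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.corrcoef(diffs)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
    else:
        corr = np.ones((1, 1))
    # ensure positive semi-definite for sampling
    w, v = np.linalg.eigh(corr)
    chol = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((mc_draws, k)) @ chol.T
    s = np.sqrt(rng.chisquare(df, mc_draws) / df)
    max_abs = np.max(np.abs(z), axis=1) / s
    p_adj = np.array([np.mean(max_abs >= abs(t)) for t in t_stats])
    crit = float(np.quantile(max_abs, 1.0 - alpha))
    return DunnettResult(
        t_stats=t_stats,
        p_adjusted=p_adj,
        critical_value=crit,
        df=df,
        alpha=alpha,
        mc_draws=mc_draws,
    )


# ---------------------------------------------------------------------------
# validation table
# ---------------------------------------------------------------------------

@dataclass
class PairedSample:
    """One participant's criterion and device values for validation."""

    participant_id: str
    criterion_paee: float
    device_paee: dict[str, float]
    weight_kg: float | None = None
    criterion_pal: float | None = None
    device_pal: dict[str, float] | None = None


@dataclass
class AgreementResult:
    """Agreement statistics for one device and measure vs the criterion."""

    device_id: str
    measure: str
    n: int
    device_mean: float
    device_sd: float
    mean_diff: float
    dunnett_p: float
    significant: bool
    mape_mean_pct: float
    mape_sd_pct: float
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    partial_r_weight: float | None
    partial_p_weight: float | None
    ba_bias: float
    ba_loa_lower: float
    ba_loa_upper: float
    ba_prop_r: float
    ba_prop_p: float


def _complete_cases(study, getter):
    """Per-device complete-case vectors: (ids, criterion, device, weight)."""
    out = {}
    for s in study:
        vals = getter(s)
        if vals is None:
            continue
        for dev, v in vals.items():
            if v is None or not np.isfinite(v):
                continue
            out.setdefault(dev, []).append((s.participant_id, v, s))
    return out


def build_validation_table(
    study: list[PairedSample],
    alpha: float = 0.05,
    mc_draws: int = 100_000,
    seed: int | None = None,
    paired: bool = False,
) -> list[AgreementResult]:
    """Run the full agreement suite for every device and measure.

    Measures covered: absolute PAEE always; PAEE per kg when weights are
    present; PAL when PAL data are present.  Each device uses its own
    complete cases.  Significance is two-sided at ``alpha`` on the
    Dunnett-adjusted p.
    """
    if not study:
        raise ValueError("empty study")

    measures: list[tuple[str, callable, callable]] = [
        ("paee", lambda s: s.criterion_paee, lambda s: s.device_paee)
    ]
    if all(s.weight_kg for s in study):
        measures.append(
            (
                "paee_per_wt",
                lambda s: s.criterion_paee / s.weight_kg,
                lambda s: {k: v / s.weight_kg for k, v in s.device_paee.items()},
            )
        )
    if all(s.criterion_pal is not None and s.device_pal is not None for s in study):
        measures.append(("pal", lambda s: s.criterion_pal, lambda s: s.device_pal))

    results: list[AgreementResult] = []
    for m_i, (measure, crit_of, devs_of) in enumerate(measures):
        per_dev = _complete_cases(study, devs_of)
        devices = sorted(per_dev)
        crit_vecs = {}
        dev_vecs = {}
        wt_vecs = {}
        for dev in devices:
            rows = per_dev[dev]
            crit_vecs[dev] = np.array([crit_of(s) for _, _, s in rows])
            dev_vecs[dev] = np.array([v for _, v, _ in rows])
            wt_vecs[dev] = np.array(
                [s.weight_kg if s.weight_kg else np.nan for _, _, s in rows]
            )

        dn_seed = None if seed is None else seed + m_i
        ns = {len(v) for v in dev_vecs.values()}
        if paired and len(ns) == 1:
            full_crit = next(iter(crit_vecs.values()))
            dn = dunnett_paired(
                full_crit,
                np.vstack([dev_vecs[d] for d in devices]),
                alpha=alpha,
                mc_draws=mc_draws,
                seed=dn_seed,
            )
        else:
            # classical Dunnett: criterion values (complete-case union) as
            # the control group, device vectors as treatment groups
            control = np.array([crit_of(s) for s in study])
            dn = dunnett_many_to_one(
                control,
                [dev_vecs[d] for d in devices],
                alpha=alpha,
                mc_draws=mc_draws,
                seed=dn_seed,
            )

        for i, dev in enumerate(devices):
            c = crit_vecs[dev]
            d = dev_vecs[dev]
            w = wt_vecs[dev]
            mean_pct, sd_pct = mape(d, c)
            r, rp, rho, rhop = correlations(c, d)
            if np.all(np.isfinite(w)) and len(d) >= 4:
                pr_w, pp_w = partial_correlation(c, d, w)
            else:
                pr_w, pp_w = None, None
            bias, loa, prop_r, prop_p = bland_altman_modified(c, d)
            p_adj = float(dn.p_adjusted[i])
            results.append(
                AgreementResult(
                    device_id=dev,
                    measure=measure,
                    n=len(d),
                    device_mean=float(np.mean(d)),
                    device_sd=float(np.std(d, ddof=1)),
                    mean_diff=float(np.mean(d) - np.mean(c)),
                    dunnett_p=p_adj,
                    significant=p_adj < alpha,
                    mape_mean_pct=mean_pct,
                    mape_sd_pct=sd_pct,
                    pearson_r=r,
                    pearson_p=rp,
                    spearman_rho=rho,
                    spearman_p=rhop,
                    partial_r_weight=pr_w,
                    partial_p_weight=pp_w,
                    ba_bias=bias,
                    ba_loa_lower=loa[0],
                    ba_loa_upper=loa[1],
                    ba_prop_r=prop_r,
                    ba_prop_p=prop_p,
                )
            )
    return results


def results_to_frame(results: list[AgreementResult]) -> pd.DataFrame:
    """Tabulate agreement results, one row per device and measure."""
    cols = [f.name for f in dc_fields(AgreementResult)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results])


class DeviceValidation:
    """Validation study model: devices vs one criterion method.

    Parameters
    ----------
    study : list of PairedSample
        Per-participant criterion and device values.
    alpha : float
        Two-sided significance level for the Dunnett comparisons.
    paired : bool
        Use the repeated-measures Dunnett variant (the devices and the
        criterion are measured on the same participants) instead of the
        classical independent-groups test.
    """

    def __init__(
        self,
        study: list[PairedSample],
        alpha: float = 0.05,
        mc_draws: int = 100_000,
        paired: bool = False,
    ):
        self.study = study
        self.alpha = alpha
        self.mc_draws = mc_draws
        self.paired = paired

    @classmethod
    def from_dataframe(
        cls,
        devices: pd.DataFrame,
        criterion: pd.DataFrame,
        **kwargs,
    ) -> "DeviceValidation":
        """Build from tidy tables.

        ``devices``: columns participant_id, device_id, paee_kcal
        (optionally pal).  ``criterion``: participant_id, criterion_paee,
        weight_kg (optionally criterion_pal).
        """
        crit = criterion.set_index("participant_id")
        study = []
        for pid, grp in devices.groupby("participant_id"):
            if pid not in crit.index:
                raise KeyError(f"participant {pid!r} missing from criterion table")
            row = crit.loc[pid]
            dev_paee = dict(zip(grp["device_id"], grp["paee_kcal"]))
            dev_pal = (
                dict(zip(grp["device_id"], grp["pal"])) if "pal" in grp else None
            )
            study.append(
                PairedSample(
                    participant_id=str(pid),
                    criterion_paee=float(row["criterion_paee"]),
                    device_paee=dev_paee,
                    weight_kg=float(row["weight_kg"]) if "weight_kg" in row else None,
                    criterion_pal=(
                        float(row["criterion_pal"]) if "criterion_pal" in row else None
                    ),
                    device_pal=dev_pal,
                )
            )
        return cls(study, **kwargs)

    def fit(self, seed: int | None = None) -> "ValidationResults":
        results = build_validation_table(
            self.study,
            alpha=self.alpha,
            mc_draws=self.mc_draws,
            seed=seed,
            paired=self.paired,
        )
        return ValidationResults(self, results)


class ValidationResults:
    """Fitted validation study; tabular access plus a printable summary."""

    def __init__(self, model: DeviceValidation, results: list[AgreementResult]):
        self.model = model
        self.results = results

    def to_frame(self) -> pd.DataFrame:
        return results_to_frame(self.results)

    def for_measure(self, measure: str) -> list[AgreementResult]:
        return [r for r in self.results if r.measure == measure]

    def summary(self) -> str:
        crit = np.array([s.criterion_paee for s in self.model.study])
        lines = [
            "Device validation vs criterion PAEE "
            f"({crit.mean():.1f} ± {crit.std(ddof=1):.1f} kcal/day, "
            f"n={len(crit)})",
            f"{'device':<22}{'measure':<12}{'mean±SD':>18}{'Δ':>9}"
            f"{'p(Dunnett)':>12}{'MAPE%':>8}{'r':>7}{'ρ':>7}{'prop r':>8}",
        ]
        for r in self.results:
            star = "*" if r.significant else " "
            lines.append(
                f"{r.device_id:<22}{r.measure:<12}"
                f"{r.device_mean:>10.1f}±{r.device_sd:<7.1f}"
                f"{r.mean_diff:>8.1f}{r.dunnett_p:>11.3f}{star}"
                f"{r.mape_mean_pct:>8.1f}{r.pearson_r:>7.2f}"
                f"{r.spearman_rho:>7.2f}{r.ba_prop_r:>8.2f}"
            )
        lines.append("* two-sided p < "
                     f"{self.model.alpha:g} vs criterion (Dunnett-adjusted)")
        return "\n".join(lines)
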