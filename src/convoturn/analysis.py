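"""Ratings analysis: condition means, mixed model, correlations, matched subsets.

The analysis layer mirrors a standard perceptual-rating workflow: per
participant the eight repetitions of each scheme are averaged; the cell
means enter a linear mixed model with fixed effects of FTO condition,
gender and their interaction and a participant random intercept; Spearman
correlations relate flow ratings to each stimulus's realised FTO median and
IQR; and a matched-subset grid search isolates one FTO parameter by
finding the value window holding the most NHQ/HIN stimuli whose matched
parameter does not differ between conditions, then contrasts the flow
ratings of the two groups with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "average_per_condition",
    "MixedModelResult",
    "mixed_model_ratings",
    "correlate_flow_vs_fto",
    "SubsetResult",
    "find_matched_subset",
    "compare_groups_ranksum",
]


def average_per_condition(records: pd.DataFrame) -> pd.DataFrame:
    """Mean rating per (participant, scheme, attribute) cell.

    Returns one row per cell with the cell count; missing cells in the full
    participant x scheme x attribute grid are emitted as NaN with a warning.
    """
    g = (
        records.groupby(["participant", "gender", "scheme", "attribute"], observed=True)["value"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "value", "count": "n"})
    )
    full = pd.MultiIndex.from_product(
        [
            records["participant"].unique(),
            records["scheme"].unique(),
            records["attribute"].unique(),
        ],
        names=["participant", "scheme", "attribute"],
    )
    have = pd.MultiIndex.from_frame(g[["participant", "scheme", "attribute"]])
    missing = full.difference(have)
    if len(missing):
        warnings.warn(f"{len(missing)} empty participant/scheme/attribute cells", stacklevel=2)
        gender_of = records.drop_duplicates("participant").set_index("participant")["gender"]
        filler = pd.DataFrame(
            [
                {
                    "participant": p,
                    "gender": gender_of.get(p),
                    "scheme": s,
                    "attribute": a,
                    "value": np.nan,
                    "n": 0,
                }
                for p, s, a in missing
            ]
        )
        g = pd.concat([g, filler], ignore_index=True)
    return g.sort_values(["participant", "scheme", "attribute"]).reset_index(drop=True)


@dataclass
class MixedModelResult:
    """Fixed-effect tests and pairwise condition contrasts of one attribute."""

    attribute: str
    anova: pd.DataFrame  # effect, F, df_num, df_den, p
    contrasts: pd.DataFrame  # pair, estimate, se, t, df, ci_low, ci_high, p
    fit: object  # statsmodels MixedLMResults
    ddf_method: str = "containment (between-/within-participant)"

    def summary(self) -> str:
        lines = [
            f"Mixed-effects analysis of '{self.attribute}' ratings",
            "model: value ~ scheme * gender, random intercept per participant",
            f"denominator df: {self.ddf_method}",
            "",
            self.anova.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            "",
            "pairwise condition contrasts (estimated marginal means):",
            self.contrasts.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def _wald_f(fit, names: list[str], df_den: float) -> tuple[float, int, float]:
    """Joint Wald F-test that the named fixed-effect coefficients are zero."""
    all_names = list(fit.model.exog_names)
    rows = []
    for nm in names:
        r = np.zeros(len(all_names))
        r[all_names.index(nm)] = 1.0
        rows.append(r)
    R = np.vstack(rows)
    beta = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[: len(all_names), : len(all_names)]
    v = R @ beta
    W = float(v @ np.linalg.solve(R @ cov @ R.T, v))
    q = R.shape[0]
    F = W / q
    p = float(stats.f.sf(F, q, df_den))
    return F, q, p


def mixed_model_ratings(
    cell_means: pd.DataFrame,
    attribute: str,
    holm: bool = False,
) -> MixedModelResult:
    """Fit ``value ~ scheme * gender`` with a participant random intercept.

    Fixed effects are sum-to-zero coded, so the joint Wald tests of the
    condition, gender and interaction terms are Type-III tests (matching
    lme4/lmerTest's anova up to the denominator-df method). Denominator
    degrees of freedom are containment-style: participant-level for gender,
    observation-level for within-participant terms. Pairwise scheme
    contrasts are estimated-marginal-mean differences averaged over gender,
    uncorrected by default (``holm=True`` applies a Holm correction).

    Raises a diagnostic if the design is incomplete or the fit is singular.
    """
    df = cell_means[cell_means["attribute"] == attribute].dropna(subset=["value"]).copy()
    n_part = df["participant"].nunique()
    cells = df.groupby("participant", observed=True)["scheme"].nunique()
    n_schemes = df["scheme"].nunique()
    if (cells < n_schemes).any():
        raise ValueError("every participant must have all condition cells present")
    schemes = sorted(df["scheme"].unique())
    genders = sorted(df["gender"].unique())

    model = smf.mixedlm(
        "value ~ C(scheme, Sum) * C(gender, Sum)", data=df, groups=df["participant"]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    if not np.isfinite(fit.llf) or np.any(~np.isfinite(np.asarray(fit.bse_fe))):
        raise RuntimeError("singular mixed-model fit: check the design for redundancy")

    names = fit.model.exog_names
    scheme_terms = [n for n in names if n.startswith("C(scheme, Sum)") and ":" not in n]
    gender_terms = [n for n in names if n.startswith("C(gender, Sum)") and ":" not in n]
    inter_terms = [n for n in names if ":" in n]

    # containment df: within-participant terms test against the
    # observation-level residual, the between-participant gender term
    # against the participant level
    k_fe = len(names)
    df_within = float(len(df) - n_part - (len(scheme_terms) + len(inter_terms)))
    df_between = float(n_part - len(genders))

    rows = []
    for label, terms, dden in (
        ("scheme", scheme_terms, df_within),
        ("gender", gender_terms, df_between),
        ("scheme:gender", inter_terms, df_within),
    ):
        F, q, p = _wald_f(fit, terms, dden)
        rows.append({"effect": label, "F": F, "df_num": q, "df_den": dden, "p": p})
    anova = pd.DataFrame(rows)

    # estimated marginal means per scheme, averaged over gender
    def emm_vector(scheme: str) -> np.ndarray:
        r = np.zeros(len(names))
        for g in genders:
            w = 1.0 / len(genders)
            for i, nm in enumerate(names):
                x = _design_value(nm, scheme, g, schemes, genders)
                r[i] += w * x
        return r

    cov = np.asarray(fit.cov_params())[: len(names), : len(names)]
    beta = np.asarray(fit.fe_params)
    crows = []
    for s1, s2 in itertools.combinations(schemes, 2):
        c = emm_vector(s1) - emm_vector(s2)
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        t = est / se
        p = 2.0 * float(stats.t.sf(abs(t), df_within))
        tcrit = stats.t.ppf(0.975, df_within)
        crows.append(
            {
                "pair": f"{s1} - {s2}",
                "estimate": est,
                "se": se,
                "t": t,
                "df": df_within,
                "ci_low": est - tcrit * se,
                "ci_high": est + tcrit * se,
                "p": p,
            }
        )
    contrasts = pd.DataFrame(crows)
    if holm:
        order = np.argsort(contrasts["p"].to_numpy())
        m = len(contrasts)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * contrasts["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        contrasts["p_holm"] = adj
    return MixedModelResult(attribute=attribute, anova=anova, contrasts=contrasts, fit=fit)


def _design_value(name: str, scheme: str, gender: str, schemes, genders) -> float:
    """Value of one patsy sum-coded design column at (scheme, gender).

    Sum coding drops the last (byte-order) level; its rows carry -1 on every
    column of that factor.
    """
    if name == "Intercept":
        return 1.0

    def code(level_col: str, level: str, levels) -> float:
        if level == level_col:
            return 1.0
        if level == levels[-1]:
            return -1.0
        return 0.0

    val = 1.0
    for part in name.split(":"):
        level_col = part.split("[S.", 1)[1].rstrip("]")
        if part.startswith("C(scheme, Sum)"):
            val *= code(level_col, scheme, sorted(schemes))
        elif part.startswith("C(gender, Sum)"):
            val *= code(level_col, gender, sorted(genders))
        else:
            raise ValueError(f"unexpected design column {name!r}")
    return val


def correlate_flow_vs_fto(
    records: pd.DataFrame, parameter: str = "median"
) -> tuple[float, float, int]:
    """Spearman correlation of flow ratings with the realised FTO parameter.

    Restricted to the variable-FTO schemes (NHQ, HIN) and the flow
    attribute, pooled across conversations and participants. Mid-rank ties,
    two-sided p. Returns (rho, p, n).
    """
    col = {"median": "realized_fto_median_ms", "iqr": "realized_fto_iqr_ms"}[parameter]
    sel = records[
        records["scheme"].isin(["NHQ", "HIN"]) & (records["attribute"] == "flow")
    ]
    if len(sel) < 5:
        raise ValueError(f"need >= 5 flow records of NHQ/HIN stimuli, got {len(sel)}")
    rho, p = stats.spearmanr(sel[col], sel["value"])
    return float(rho), float(p), int(len(sel))


# ------------------------------------------------------------------ rank-sum


def _ranksum_stats(
    values_a: np.ndarray, values_b: np.ndarray
) -> tuple[float, float, float, float]:
    """Rank-sum W of group A with its null mean, tie-corrected SD, and z."""
    pooled = np.concatenate([values_a, values_b])
    n_a, n_b = len(values_a), len(values_b)
    n = n_a + n_b
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n_a].sum())
    mu = n_a * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    sd = float(np.sqrt(var)) if var > 0 else 0.0
    z = (w - mu) / sd if sd > 0 else 0.0
    return w, mu, sd, float(z)


def compare_groups_ranksum(values_a, values_b) -> tuple[float, float]:
    """Wilcoxon rank-sum test between two groups: (z, two-sided p).

    Uses the normal approximation with mid-rank tie correction and a
    continuity correction in the p-value; for pooled sizes of at most 12
    the p-value comes from exact enumeration of all group assignments
    instead. Degenerate input (all values identical) gives z = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need n >= 3")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    w_obs, mu, sd, z = _ranksum_stats(a, b)
    n = len(pooled)
    if n <= 12:
        ranks = stats.rankdata(pooled)
        dev_obs = abs(w_obs - mu)
        count = total = 0
        for combo in itertools.combinations(range(n), len(a)):
            w = ranks[list(combo)].sum()
            total += 1
            if abs(w - mu) >= dev_obs - 1e-12:
                count += 1
        p = count / total
    else:
        z_cc = max(abs(w_obs - mu) - 0.5, 0.0) / sd if sd > 0 else 0.0
        p = 2.0 * float(stats.norm.sf(z_cc))
    return z, min(p, 1.0)


# ------------------------------------------------------------- subset search


@dataclass
class SubsetResult:
    """Outcome of the matched-subset window search."""

    parameter_matched: str
    interval: tuple[float, float] | None
    n_total: int
    n_nhq: int
    n_hin: int
    match_test: tuple[float, float] | None  # (z, p) on the matched parameter
    contrast_test: tuple[float, float] | None  # (z, p) on the contrast variable

    @property
    def empty(self) -> bool:
        return self.interval is None


def find_matched_subset(
    records: pd.DataFrame,
    match_on: str = "median",
    window_width_ms: float = 80.0,
    step_ms: float = 5.0,
    alpha: float = 0.05,
    max_count_diff: int = 20,
    contrast_column: str = "value",
) -> SubsetResult:
    """Find the FTO window holding the most NHQ/HIN stimuli matched on one parameter.

    Slides a window of ``window_width_ms`` in ``step_ms`` steps over the
    matched parameter's range; a window qualifies when the rank-sum test on
    the matched parameter between NHQ and HIN records has p > alpha and the
    group counts differ by at most ``max_count_diff``. Among qualifying
    windows the one with the most records wins (ties: lowest window). The
    returned result carries the rank-sum contrast on ``contrast_column``
    (flow ratings by default) between the two groups within the window.
    """
    col = {"median": "realized_fto_median_ms", "iqr": "realized_fto_iqr_ms"}[match_on]
    sel = records[records["scheme"].isin(["NHQ", "HIN"])]
    if "attribute" in sel.columns and contrast_column == "value":
        sel = sel[sel["attribute"] == "flow"]
    x = sel[col].to_numpy()
    lo0 = np.floor(x.min() / step_ms) * step_ms
    hi0 = x.max()
    best = None
    lo = lo0
    while lo <= hi0:
        hi = lo + window_width_ms
        win = sel[(sel[col] >= lo) & (sel[col] <= hi)]
        va = win.loc[win["scheme"] == "NHQ", col].to_numpy()
        vb = win.loc[win["scheme"] == "HIN", col].to_numpy()
        if len(va) >= 3 and len(vb) >= 3 and abs(len(va) - len(vb)) <= max_count_diff:
            _, p = compare_groups_ranksum(va, vb)
            if p > alpha:
                n = len(va) + len(vb)
                if best is None or n > best[0]:
                    best = (n, lo, hi)
        lo += step_ms
    if best is None:
        return SubsetResult(match_on, None, 0, 0, 0, None, None)
    _, lo, hi = best
    win = sel[(sel[col] >= lo) & (sel[col] <= hi)]
    a = win[win["scheme"] == "NHQ"]
    b = win[win["scheme"] == "HIN"]
    match_test = compare_groups_ranksum(a[col], b[col])
    contrast_test = compare_groups_ranksum(a[contrast_column], b[contrast_column])
    return SubsetResult(
        parameter_matched=match_on,
        interval=(float(lo), float(hi)),
        n_total=len(win),
        n_nhq=len(a),
        n_hin=len(b),
        match_test=match_test,
        contrast_test=contrast_test,
    )
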