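"""Block organization and the mixed-design analysis.

Per-trial measures are first organized the way the study analyzes them:
for each perturbation kind (fast / slow) the nine perturbation trials are
split into three *moments* — Early (ordinals 1-3), Intermediate (4-6),
Later (7-9) — and each moment forms three *blocks*: Pre (the control
trials immediately preceding those perturbations), P (the perturbation
trials), and Post (the controls immediately following). Every cell is the
mean of exactly three trials.

Constant error and tPV% are then analyzed, per kind x moment, with a
two-way mixed-design ANOVA: group (SG vs SSG) between participants, block
(Pre, P, Post) within. Sums of squares use the classical balanced
partition (identical to Type III in a balanced design); no sphericity
correction is applied, matching the uncorrected (2, 76) within-subject
degrees of freedom the design prints at N = 40. Effect size is partial
eta squared, ss_effect / (ss_effect + ss_error), with the conventional
bands trivial < 0.01 <= small < 0.06 <= medium <= 0.14 < large.
Corrective-submovement counts are compared between groups with
independent-samples t tests per perturbation kind; Tukey's HSD over the
ANOVA error term handles pairwise contrasts; a Shapiro-Wilk screen gates
(but never silently replaces) the parametric analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, InvalidParameterError

__all__ = [
    "MOMENTS",
    "BLOCKS",
    "EffectResult",
    "MixedAnovaResult",
    "organize_blocks",
    "mixed_anova",
    "partial_eta_sq",
    "eta_band",
    "ncor_t_test",
    "tukey_posthoc",
    "normality_gate",
    "analyze_study",
]

MOMENTS = ("Early", "Intermediate", "Later")
BLOCKS = ("Pre", "P", "Post")

_MOMENT_OF_ORDINAL = {o: MOMENTS[(o - 1) // 3] for o in range(1, 10)}


# ---------------------------------------------------------------------------
# block organization
# ---------------------------------------------------------------------------

def organize_blocks(measures: pd.DataFrame) -> pd.DataFrame:
    """Build the participant x kind x moment x block summary table.

    ``measures`` holds one row per exposure trial with columns
    ``participant, group, trial_index, kind, perturbation_ordinal, ce,
    tpv, ncor`` (kind in control/fast/slow). Returns one row per
    participant x kind x moment x block with ``ce``/``tpv`` cell means,
    plus ``ncor`` for P blocks (perturbed trials only, the only place the
    measure is defined) and an ``incomplete`` flag when a flanking control
    is missing or a constituent value is NaN.
    """
    required = {"participant", "group", "trial_index", "kind",
                "perturbation_ordinal", "ce", "tpv", "ncor"}
    missing = required - set(measures.columns)
    if missing:
        raise DataError(f"measures table missing columns: {sorted(missing)}")

    rows = []
    for (pid, grp), sub in measures.groupby(["participant", "group"], sort=True):
        by_index = sub.set_index("trial_index")
        for kind in ("fast", "slow"):
            pert = sub[sub["kind"] == kind].sort_values("perturbation_ordinal")
            for moment in MOMENTS:
                trio = pert[pert["perturbation_ordinal"].map(
                    lambda o: _MOMENT_OF_ORDINAL.get(int(o)) == moment
                    if pd.notna(o) else False)]
                cell = {b: {"ce": [], "tpv": []} for b in BLOCKS}
                ncor_vals: List[float] = []
                incomplete = len(trio) != 3
                for _, tr in trio.iterrows():
                    idx = int(tr["trial_index"])
                    cell["P"]["ce"].append(tr["ce"])
                    cell["P"]["tpv"].append(tr["tpv"])
                    ncor_vals.append(tr["ncor"])
                    for block, j in (("Pre", idx - 1), ("Post", idx + 1)):
                        if j in by_index.index and by_index.loc[j, "kind"] == "control":
                            cell[block]["ce"].append(by_index.loc[j, "ce"])
                            cell[block]["tpv"].append(by_index.loc[j, "tpv"])
                        else:
                            incomplete = True
                for block in BLOCKS:
                    ce_vals = np.asarray(cell[block]["ce"], dtype=float)
                    tpv_vals = np.asarray(cell[block]["tpv"], dtype=float)
                    flag = (incomplete or len(ce_vals) != 3
                            or np.isnan(ce_vals).any() or np.isnan(tpv_vals).any())
                    rows.append({
                        "participant": pid, "group": grp, "kind": kind,
                        "moment": moment, "block": block,
                        "ce": float(np.nanmean(ce_vals)) if len(ce_vals) else np.nan,
                        "tpv": float(np.nanmean(tpv_vals)) if len(tpv_vals) else np.nan,
                        "ncor": (float(np.nanmean(ncor_vals))
                                 if block == "P" and len(ncor_vals) else np.nan),
                        "incomplete": bool(flag),
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectResult:
    name: str
    ss: float
    df_num: int
    df_den: int
    ms: float
    f: float
    p: float
    eta_p_sq: float
    band: str
    degenerate: bool = False


@dataclass
class MixedAnovaResult:
    effects: Dict[str, EffectResult]
    cell_means: pd.DataFrame
    error_terms: Dict[str, Tuple[float, int]]   # name -> (MS_error, df)
    posthoc: Optional[pd.DataFrame] = None


def partial_eta_sq(ss_effect: float, ss_error: float) -> Tuple[float, str]:
    """ss_effect / (ss_effect + ss_error) with its conventional band label."""
    if ss_effect < 0 or ss_error < 0:
        raise InvalidParameterError("sums of squares must be >= 0")
    if ss_effect == 0 and ss_error == 0:
        return float("nan"), "undefined"
    eta = ss_effect / (ss_effect + ss_error)
    return eta, eta_band(eta)


def eta_band(eta: float) -> str:
    """Bands: trivial < 0.01 <= small < 0.06 <= medium <= 0.14 < large."""
    if np.isnan(eta):
        return "undefined"
    if eta < 0.01:
        return "trivial"
    if eta < 0.06:
        return "small"
    if eta <= 0.14:
        return "medium"
    return "large"


def _f_p(ss_eff: float, df_eff: int, ss_err: float, df_err: int
         ) -> Tuple[float, float, float, bool]:
    """(MS, F, p, degenerate) guarding the all-constant case."""
    ms_eff = ss_eff / df_eff if df_eff else 0.0
    ms_err = ss_err / df_err if df_err else 0.0
    if ms_err <= 0:
        if ms_eff <= 0:
            return ms_eff, 0.0, 1.0, True      # no variance anywhere
        return ms_eff, float("inf"), 0.0, True
    f = ms_eff / ms_err
    return ms_eff, f, float(sps.f.sf(f, df_eff, df_err)), False


def mixed_anova(cells: pd.DataFrame, dv: str,
                group_col: str = "group", block_col: str = "block",
                subject_col: str = "participant") -> MixedAnovaResult:
    """Two-way mixed-design ANOVA: one between factor, one within factor.

    Requires a balanced complete table (one value per subject x block,
    equal group sizes); missing or duplicated cells raise — no silent
    imputation. Returns F, uncorrected df, p and partial eta squared per
    effect, plus the error terms Tukey contrasts need.
    """
    df = cells[[subject_col, group_col, block_col, dv]].copy()
    if df[dv].isna().any():
        raise DataError(f"missing values in dv {dv!r}")
    groups = sorted(df[group_col].unique())
    blocks = list(pd.unique(cells[block_col]))
    subjects = sorted(df[subject_col].unique())
    g, b, n_subj = len(groups), len(blocks), len(subjects)
    if g < 2 or b < 2:
        raise DataError("need at least 2 groups and 2 blocks")

    pivot = df.pivot_table(index=subject_col, columns=block_col, values=dv,
                           aggfunc="count")
    if pivot.shape != (n_subj, b) or not (pivot.to_numpy() == 1).all():
        raise DataError("design must have exactly one value per subject x block")
    subj_group = df.groupby(subject_col)[group_col].agg(lambda s: s.iloc[0])
    sizes = subj_group.value_counts()
    if sizes.nunique() != 1:
        raise DataError(f"unbalanced groups: {sizes.to_dict()}")
    n = int(sizes.iloc[0])

    y = df.pivot(index=subject_col, columns=block_col, values=dv)[blocks]
    values = y.to_numpy(dtype=float)                       # subjects x blocks
    grp_of = subj_group.loc[y.index].to_numpy()
    grand = values.mean()

    subj_means = values.mean(axis=1)
    group_means = np.array([subj_means[grp_of == gr].mean() for gr in groups])
    block_means = values.mean(axis=0)
    cell_means = np.array([[values[grp_of == gr, j].mean() for j in range(b)]
                           for gr in groups])

    ss_total = float(((values - grand) ** 2).sum())
    ss_between_subj = float(b * ((subj_means - grand) ** 2).sum())
    ss_group = float(n * b * ((group_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group
    ss_block = float(n_subj * ((block_means - grand) ** 2).sum())
    inter_dev = (cell_means - group_means[:, None] - block_means[None, :] + grand)
    ss_inter = float(n * (inter_dev ** 2).sum())
    ss_error = ss_total - ss_between_subj - ss_block - ss_inter
    ss_error = max(ss_error, 0.0)

    df_group, df_subj = g - 1, n_subj - g
    df_block = b - 1
    df_inter = (g - 1) * (b - 1)
    df_error = df_subj * df_block

    effects = {}
    for name, ss_eff, df_eff, ss_err, df_err in (
        ("group", ss_group, df_group, ss_subj_within, df_subj),
        ("block", ss_block, df_block, ss_error, df_error),
        ("interaction", ss_inter, df_inter, ss_error, df_error),
    ):
        ms, f, p, degen = _f_p(ss_eff, df_eff, ss_err, df_err)
        eta, band = partial_eta_sq(max(ss_eff, 0.0), max(ss_err, 0.0)) \
            if (ss_eff > 0 or ss_err > 0) else (float("nan"), "undefined")
        effects[name] = EffectResult(name, ss_eff, df_eff, df_err, ms, f, p,
                                     eta, band, degenerate=degen)
    cm = pd.DataFrame(cell_means, index=pd.Index(groups, name=group_col),
                      columns=pd.Index(blocks, name=block_col))
    error_terms = {
        "group": (ss_subj_within / df_subj if df_subj else 0.0, df_subj),
        "within": (ss_error / df_error if df_error else 0.0, df_error),
    }
    return MixedAnovaResult(effects=effects, cell_means=cm,
                            error_terms=error_terms)


# ---------------------------------------------------------------------------
# post hoc and companions
# ---------------------------------------------------------------------------

def tukey_posthoc(result: MixedAnovaResult, effect: str = "auto",
                  n_per_group: Optional[int] = None) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons via the studentized range.

    ``effect='block'`` compares within-factor marginal means against the
    within-subject error term; ``effect='interaction'`` compares all
    group x block cell means. ``'auto'`` decomposes the interaction when
    it is significant at 0.05 and falls back to the block marginals
    otherwise. ``n_per_group`` (subjects per group) is required and is
    inferred from the error-term df when omitted.
    """
    cm = result.cell_means
    g, b = cm.shape
    ms_err, df_err = result.error_terms["within"]
    if n_per_group is None:
        n_per_group = df_err // ((g) * (b - 1)) + 1 if g else None
        # df_err = g*(n-1)*(b-1)  =>  n = df_err / (g*(b-1)) + 1
        n_per_group = int(round(df_err / (g * (b - 1)))) + 1
    n_subj = g * n_per_group

    if effect == "auto":
        inter = result.effects["interaction"]
        effect = "interaction" if inter.p < 0.05 else "block"

    if effect == "block":
        means = cm.mean(axis=0)
        labels = list(means.index)
        n_per_mean = n_subj
    elif effect == "interaction":
        means = cm.stack()
        labels = [f"{gr}:{bl}" for gr, bl in means.index]
        n_per_mean = n_per_group
    else:
        raise InvalidParameterError("effect must be 'block', 'interaction' or 'auto'")

    k = len(means)
    vals = means.to_numpy(dtype=float)
    se = np.sqrt(ms_err / n_per_mean)
    rows = []
    for (i, j) in itertools.combinations(range(k), 2):
        diff = vals[i] - vals[j]
        if se > 0:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_err))
        else:
            q, p = 0.0, 1.0
        rows.append({"a": labels[i], "b": labels[j], "mean_a": vals[i],
                     "mean_b": vals[j], "diff": diff, "q": q, "p_adj": p,
                     "significant": p < 0.05})
    out = pd.DataFrame(rows)
    out.attrs["effect"] = effect
    return out


def ncor_t_test(block_summary: pd.DataFrame, kind: str,
                moment: Optional[str] = None) -> Dict[str, float]:
    """Independent-samples t test (pooled variance, two-sided) comparing
    SG vs SSG mean correction counts on perturbed trials of one kind.

    ``moment=None`` averages a participant's P-block means across the
    three moments (the kind-level comparison); otherwise a single moment
    is tested. Zero variance in both groups with equal means returns the
    t = 0, p = 1 convention.
    """
    sub = block_summary[(block_summary["kind"] == kind)
                        & (block_summary["block"] == "P")]
    if moment is not None:
        sub = sub[sub["moment"] == moment]
    per_part = sub.groupby(["participant", "group"])["ncor"].mean().reset_index()
    a = per_part.loc[per_part["group"] == "SG", "ncor"].to_numpy(dtype=float)
    c = per_part.loc[per_part["group"] == "SSG", "ncor"].to_numpy(dtype=float)
    if len(a) < 2 or len(c) < 2:
        raise DataError("need >= 2 participants per group")
    df = len(a) + len(c) - 2
    if np.var(a, ddof=1) == 0 and np.var(c, ddof=1) == 0:
        if a.mean() == c.mean():
            return {"t": 0.0, "df": df, "p": 1.0,
                    "mean_sg": float(a.mean()), "mean_ssg": float(c.mean())}
    t, p = sps.ttest_ind(a, c, equal_var=True)
    return {"t": float(t), "df": df, "p": float(p),
            "mean_sg": float(a.mean()), "mean_ssg": float(c.mean())}


def normality_gate(cells: pd.DataFrame, dv: str, alpha: float = 0.05,
                   group_col: str = "group", block_col: str = "block"
                   ) -> Dict[str, object]:
    """Shapiro-Wilk screen per group x block cell of one dv.

    Reports the minimum p across testable cells and a proceed flag
    (min p > alpha). Degenerate cells (n < 3 or constant) are skipped with
    a warning entry; the gate never switches the analysis to a
    nonparametric alternative — it only reports.
    """
    results = {}
    warnings: List[str] = []
    for (gr, bl), sub in cells.groupby([group_col, block_col]):
        vals = sub[dv].dropna().to_numpy(dtype=float)
        key = f"{gr}:{bl}"
        if len(vals) < 3:
            warnings.append(f"{key}: n={len(vals)} < 3, skipped")
            continue
        if np.ptp(vals) == 0:
            warnings.append(f"{key}: constant values, skipped")
            continue
        results[key] = float(sps.shapiro(vals).pvalue)
    min_p = min(results.values()) if results else float("nan")
    return {"per_cell_p": results, "min_p": min_p,
            "proceed": bool(results) and min_p > alpha,
            "warnings": warnings, "alpha": alpha}


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

def analyze_study(block_summary: pd.DataFrame, alpha: float = 0.05) -> Dict:
    """Run the complete inferential battery on a block-summary table.

    Per perturbation kind: one t test on correction counts per moment and
    at the kind level; per kind x moment: mixed ANOVAs on CE and tPV% with
    Tukey decomposition and the normality screen. Returns a nested dict of
    results keyed by kind / moment / measure.
    """
    usable = block_summary[~block_summary["incomplete"]]
    out: Dict = {"alpha": alpha, "kinds": {}}
    for kind in ("fast", "slow"):
        kind_res: Dict = {"ncor_overall": ncor_t_test(usable, kind), "moments": {}}
        for moment in MOMENTS:
            cells = usable[(usable["kind"] == kind)
                           & (usable["moment"] == moment)]
            mom: Dict = {"ncor": ncor_t_test(usable, kind, moment)}
            for dv in ("ce", "tpv"):
                res = mixed_anova(cells, dv)
                res.posthoc = tukey_posthoc(res, effect="auto")
                mom[dv] = {"anova": res, "normality": normality_gate(cells, dv)}
            kind_res["moments"][moment] = mom
        out["kinds"][kind] = kind_res
    return out
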