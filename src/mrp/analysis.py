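"""Report statistics computed from a canonical response table: per-participant
Type 1 / Type 2 AUC summaries, per-dxc proportion curves with bin-wise tests,
per-image-pair delta-tdxc classification, and likelihood-ratio plumbing for
externally fitted mixed models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import sdt
from .exceptions import InsufficientDataError
from .design import ECCENTRICITY_ORDER

log = logging.getLogger(__name__)

#: figure-annotation significance thresholds (fixed constants, uncorrected)
STAR_ALPHA = 0.003
DOUBLE_STAR_ALPHA = 0.0001


def delta_tdxc(original_tdxc, modified_tdxc) -> float:
    """Mean tdxc(original) - mean tdxc(modified) for one image pair."""
    o = np.asarray(original_tdxc, dtype=float)
    m = np.asarray(modified_tdxc, dtype=float)
    if o.size == 0 or m.size == 0:
        raise InsufficientDataError("both tdxc samples must be non-empty")
    return float(o.mean() - m.mean())


def ttest_2sample(a, b, equal_var: bool = True, axis: int = -1):
    """Two-sample t-test p-value(s); Student by default, Welch behind the flag.

    Shared by the image-pair classifier, the proportion-curve tests and the
    null-calibration helper so that calibration exercises the same routine.
    """
    import warnings

    with warnings.catch_warnings():
        # near-constant cells are routine with 8-level discrete ratings;
        # scipy then returns NaN p-values, which callers treat as untestable
        warnings.filterwarnings("ignore", message="Precision loss occurred",
                                category=RuntimeWarning)
        return stats.ttest_ind(a, b, equal_var=equal_var, axis=axis).pvalue


@dataclass(frozen=True)
class ImagePairResult:
    pair_id: str
    delta_tdxc_congruent: float
    delta_tdxc_incongruent: float
    p_congruent: float
    p_incongruent: float
    category: str | None          # grey | blue | red | black | None (untestable)
    interaction_flag: bool | None

    def to_dict(self):
        return asdict(self)


def _categorize(p_c, p_i, alpha):
    sig_c, sig_i = p_c < alpha, p_i < alpha
    if sig_c and sig_i:
        return "black"
    if sig_c:
        return "blue"
    if sig_i:
        return "red"
    return "grey"


def _interaction_p(df, ss_type: int = 2) -> float:
    """p-value of the patch_type x congruence interaction (OLS ANOVA)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols("tdxc ~ C(patch_type) * C(congruence)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)
    return float(table.loc["C(patch_type):C(congruence)", "PR(>F)"])


def classify_image_pair(responses: pd.DataFrame, alpha: float = 0.05,
                        equal_var: bool = True, interaction: bool = True,
                        ss_type: int = 2) -> ImagePairResult:
    """Classify one image pair from its original/modified probe responses.

    Within each congruence condition the original and modified tdxc samples
    are compared with a two-sample t-test; the colour category records which
    of the two tests is significant at ``alpha`` (grey: neither, blue: only
    congruent, red: only incongruent, black: both).  Cells with fewer than 2
    observations make the pair untestable (category None).  The interaction
    flag comes from the patch_type x congruence term of a two-way ANOVA.
    """
    df = responses[responses["patch_type"].isin(["original", "modified"])].copy()
    pair_id = str(df["image_pair_id"].iloc[0]) if len(df) else ""
    df["tdxc"] = sdt.transform_tdxc(df["dxc"].to_numpy())
    df = df.rename(columns={"initial_congruence": "congruence"}) \
        if "initial_congruence" in df.columns else df

    cells = {}
    for cong in ("congruent", "incongruent"):
        for ptype in ("original", "modified"):
            cells[cong, ptype] = df.loc[
                (df["congruence"] == cong) & (df["patch_type"] == ptype),
                "tdxc"].to_numpy()

    deltas, ps = {}, {}
    testable = True
    for cong in ("congruent", "incongruent"):
        o, m = cells[cong, "original"], cells[cong, "modified"]
        deltas[cong] = (float(o.mean() - m.mean())
                        if o.size and m.size else float("nan"))
        if o.size < 2 or m.size < 2:
            ps[cong] = float("nan")
            testable = False
        else:
            ps[cong] = float(ttest_2sample(o, m, equal_var=equal_var))

    category = _categorize(ps["congruent"], ps["incongruent"], alpha) \
        if testable else None
    iflag = None
    if interaction and testable:
        iflag = bool(_interaction_p(df, ss_type) < alpha)
    return ImagePairResult(pair_id, deltas["congruent"], deltas["incongruent"],
                           ps["congruent"], ps["incongruent"], category, iflag)


def classify_all_pairs(responses: pd.DataFrame, alpha: float = 0.05,
                       equal_var: bool = True,
                       interaction: bool = True) -> pd.DataFrame:
    out = []
    for pair_id, grp in responses.groupby("image_pair_id", sort=True):
        if not grp["patch_type"].isin(["original", "modified"]).any():
            continue
        out.append(classify_image_pair(grp, alpha, equal_var, interaction).to_dict())
    return pd.DataFrame(out)


def null_classifier_fpr(n_reps: int = 10_000, n_per_cell: int = 15,
                        alpha: float = 0.05, equal_var: bool = True,
                        seed: int = 0) -> float:
    """Per-test false-positive rate of the pair classifier under a true null.

    Draws ``n_reps`` original/modified cell pairs from one common normal
    distribution and runs the classifier's own two-sample t-test on each
    (vectorized via the shared :func:`ttest_2sample`).
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n_reps, n_per_cell))
    b = rng.normal(size=(n_reps, n_per_cell))
    p = ttest_2sample(a, b, equal_var=equal_var, axis=-1)
    return float((p < alpha).mean())


# ---------------------------------------------------------------------------
# per-dxc proportion curves

def _participant_proportions(df: pd.DataFrame) -> pd.DataFrame:
    """participant x dxc proportion matrix (rows sum to 1)."""
    counts = (df.groupby(["participant_id", "dxc"]).size()
              .unstack("dxc", fill_value=0)
              .reindex(columns=list(sdt.DXC_LEVELS), fill_value=0))
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        log.warning("excluding %d participant(s) with no responses in a curve",
                    int(empty.sum()))
        counts = counts.loc[~empty]
        totals = totals.loc[~empty]
    return counts.div(totals, axis=0)


def proportion_curves(responses: pd.DataFrame, curve_a, curve_b,
                      labels: tuple[str, str] = ("a", "b"),
                      eccentricity: str | None = None,
                      equal_var: bool = True) -> pd.DataFrame:
    """Mean +/- SEM response proportions per dxc bin for two probe groups.

    ``curve_a``/``curve_b`` are collections of patch types (e.g.
    ``{"present", "original"}`` vs ``{"null"}``).  Proportions are computed
    per participant (each participant's 8 bins sum to 1 within a curve) and
    compared bin-wise across participants with two-sample t-tests, flagged at
    the fixed 0.003 (*) and 0.0001 (**) thresholds.
    """
    df = responses[~responses["is_catch"].astype(bool)] \
        if "is_catch" in responses.columns else responses
    if eccentricity is not None:
        df = df[df["eccentricity_class"] == eccentricity]
    props = {}
    for label, group in zip(labels, (curve_a, curve_b)):
        props[label] = _participant_proportions(df[df["patch_type"].isin(set(group))])

    la, lb = labels
    rows = []
    for dxc in sdt.DXC_LEVELS:
        a = props[la][dxc].to_numpy()
        b = props[lb][dxc].to_numpy()
        p = float(ttest_2sample(a, b, equal_var=equal_var)) \
            if a.size > 1 and b.size > 1 else float("nan")
        flag = "**" if p < DOUBLE_STAR_ALPHA else ("*" if p < STAR_ALPHA else "")
        rows.append({
            "dxc": dxc,
            f"mean_{la}": a.mean() if a.size else float("nan"),
            f"sem_{la}": stats.sem(a) if a.size > 1 else float("nan"),
            f"mean_{lb}": b.mean() if b.size else float("nan"),
            f"sem_{lb}": stats.sem(b) if b.size > 1 else float("nan"),
            "p": p, "flag": flag,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# AUC summaries

def _participant_aucs(df: pd.DataFrame, task: str) -> tuple[float, float]:
    """(type1, type2) AUC for one participant's responses; NaN when undefined."""
    signal_types, noise_types = sdt.TASKS[task]
    sig = df.loc[df["patch_type"].isin(signal_types), "dxc"].to_numpy()
    noi = df.loc[df["patch_type"].isin(noise_types), "dxc"].to_numpy()
    if sig.size == 0 or noi.size == 0:
        return float("nan"), float("nan")
    t1 = sdt.type1_roc(sig, noi).auc
    correct = df.apply(
        lambda r: sdt.classify_correct(r["decision"], r["patch_type"], task), axis=1)
    conf = df["confidence"].to_numpy()
    in_task = correct.notna().to_numpy()
    corr_conf = conf[in_task & (correct == True).to_numpy()]  # noqa: E712
    inc_conf = conf[in_task & (correct == False).to_numpy()]  # noqa: E712
    if corr_conf.size == 0 or inc_conf.size == 0:
        return t1, float("nan")    # Type 2 undefined: reported missing, not 1.0
    return t1, sdt.type2_roc(corr_conf, inc_conf).auc


def auc_summary(responses: pd.DataFrame, task: str,
                strata: bool = True,
                congruence: str | None = None) -> pd.DataFrame:
    """Per-participant Type 1/Type 2 AUCs, pooled and (optionally) per stratum.

    Responses are pooled across a participant's images within each
    eccentricity stratum; the "all" stratum pools across eccentricities.
    ``congruence`` restricts to one initial-image condition.
    """
    df = responses[~responses["is_catch"].astype(bool)] \
        if "is_catch" in responses.columns else responses
    if congruence is not None:
        df = df[df["initial_congruence"] == congruence]
    strata_list = ["all"] + (list(ECCENTRICITY_ORDER) if strata else [])
    rows = []
    for part, grp in df.groupby("participant_id", sort=True):
        for stratum in strata_list:
            sub = grp if stratum == "all" else grp[grp["eccentricity_class"] == stratum]
            if len(sub) == 0:
                continue
            t1, t2 = _participant_aucs(sub, task)
            rows.append({"participant_id": part, "task": task, "stratum": stratum,
                         "type1_auc": t1, "type2_auc": t2})
    return pd.DataFrame(rows)


def summarize_auc(per_participant: pd.DataFrame,
                  chance: float = 0.5) -> pd.DataFrame:
    """Group mean, SEM and one-sample t vs chance, per stratum and AUC kind."""
    rows = []
    for (task, stratum), grp in per_participant.groupby(["task", "stratum"]):
        for kind in ("type1_auc", "type2_auc"):
            vals = grp[kind].dropna().to_numpy()
            if vals.size == 0:
                continue
            if vals.size > 1 and vals.std() > 0:
                t, p = stats.ttest_1samp(vals, chance)
            else:
                t, p = float("nan"), float("nan")
            rows.append({"task": task, "stratum": stratum, "measure": kind,
                         "n": vals.size, "mean": float(vals.mean()),
                         "sem": float(stats.sem(vals)) if vals.size > 1 else float("nan"),
                         "t_vs_chance": float(t), "p_vs_chance": float(p)})
    return pd.DataFrame(rows)


def paired_comparison(per_participant: pd.DataFrame, measure: str = "type1_auc",
                      stratum: str = "all"):
    """Paired t-test between two conditions coded in a 'condition' column."""
    df = per_participant[per_participant["stratum"] == stratum]
    conds = sorted(df["condition"].unique())
    if len(conds) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conds}")
    wide = df.pivot(index="participant_id", columns="condition", values=measure).dropna()
    t, p = stats.ttest_rel(wide[conds[0]], wide[conds[1]])
    return float(t), float(p)


# ---------------------------------------------------------------------------
# model-comparison plumbing and modelling export

def lrt_chi2(loglik_full: float, loglik_reduced: float,
             df_diff: int) -> tuple[float, float]:
    """Likelihood-ratio chi-squared and p-value for nested model comparison."""
    if df_diff < 1:
        raise ValueError("df_diff must be >= 1")
    chi2 = 2.0 * (loglik_full - loglik_reduced)
    if chi2 < 0:
        raise ValueError(
            "negative chi-squared: full model must have the higher log-likelihood")
    return float(chi2), float(stats.chi2.sf(chi2, df_diff))


def modelling_export(responses: pd.DataFrame,
                     image_stats: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tidy per-pair x congruence table of delta-tdxc for external mixed models.

    Columns: image_pair_id, congruence, delta_tdxc, n_original, n_modified,
    plus any per-pair image statistics merged on image_pair_id.
    """
    df = responses[responses["patch_type"].isin(["original", "modified"])].copy()
    df["tdxc"] = sdt.transform_tdxc(df["dxc"].to_numpy())
    rows = []
    for (pair, cong), grp in df.groupby(["image_pair_id", "initial_congruence"]):
        o = grp.loc[grp["patch_type"] == "original", "tdxc"].to_numpy()
        m = grp.loc[grp["patch_type"] == "modified", "tdxc"].to_numpy()
        rows.append({"image_pair_id": pair, "congruence": cong,
                     "delta_tdxc": float(o.mean() - m.mean())
                     if o.size and m.size else float("nan"),
                     "n_original": o.size, "n_modified": m.size})
    out = pd.DataFrame(rows)
    if image_stats is not None:
        out = out.merge(image_stats, left_on="image_pair_id",
                        right_on="pair_id", how="left")
    return out
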