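"""Selectivity statistics and method comparisons.

Selectivity of a region is PSC(preferred category) - PSC(contrast
category), measured on the held-out evaluation run. Per-region paired
t-tests (Bonferroni corrected over the 18 regions) establish selectivity;
a category x hemisphere ANOVA with subject as a random factor
(constrained / Type III sums of squares) quantifies domain and
hemispheric effects; method comparisons pit connectivity-defined regions
against localizer- and atlas-defined ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glm import BetaMap, compute_psc
from .synth.registry import CONDITIONS, FROIRegistry

__all__ = [
    "TestResult",
    "AnovaResult",
    "MethodComparison",
    "selectivity_table",
    "paired_ttest",
    "one_sample_ttest",
    "bonferroni_threshold",
    "anova_selectivity",
    "compare_methods",
]

logger = logging.getLogger(__name__)

ANOVA_ROWS = (
    "Domain",
    "Hemisphere",
    "Subject",
    "Domain*Hemisphere",
    "Domain*Subject",
    "Hemisphere*Subject",
    "Error",
    "Total",
)


@dataclass(frozen=True)
class TestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    n: int


def paired_ttest(x, y) -> TestResult:
    """Two-sided paired t-test as a one-sample t on the differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-d samples with n >= 2")
    return one_sample_ttest(x - y)


def one_sample_ttest(d) -> TestResult:
    d = np.asarray(d, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("need a 1-d sample with n >= 2")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: t undefined")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return TestResult(t=float(t), df=n - 1, p=float(p), mean_diff=float(d.mean()), n=n)


def bonferroni_threshold(alpha: float = 0.05, m: int = 18) -> float:
    """Family-wise corrected per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def selectivity_table(
    registry: FROIRegistry,
    frois_by_method: dict[str, dict[tuple[str, str], np.ndarray]],
    eval_betamaps: dict[str, BetaMap],
) -> pd.DataFrame:
    """One row per subject x region x method with per-condition PSC and
    selectivity, computed from the evaluation run's betas.

    ``frois_by_method[method][(subject, froi_id)]`` is the vertex set.
    Missing regions are skipped with a warning.
    """
    rows = []
    for method, sets in frois_by_method.items():
        for subject, bm in eval_betamaps.items():
            for entry in registry:
                verts = sets.get((subject, entry.froi_id))
                if verts is None or len(verts) == 0:
                    logger.warning("missing fROI %s/%s for %s", method, entry.froi_id, subject)
                    continue
                pscs = {c: compute_psc(bm, verts, c) for c in CONDITIONS}
                row = {
                    "subject": subject,
                    "froi": entry.froi_id,
                    "method": method,
                    "hemisphere": entry.hemisphere,
                    "category": entry.category,
                    **{f"psc_{c}": v for c, v in pscs.items()},
                }
                row["selectivity"] = (
                    pscs[entry.preferred_condition] - pscs[entry.contrast_condition]
                )
                rows.append(row)
    return pd.DataFrame(rows)


def _sum_code(labels: np.ndarray, levels: list) -> np.ndarray:
    """Deviation (sum-to-zero) coding: L-1 columns, last level coded -1."""
    M = np.zeros((len(labels), len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        M[labels == lev, j] = 1.0
    M[labels == levels[-1], :] = -1.0
    return M


def _interaction(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return np.einsum("ni,nj->nij", A, B).reshape(len(A), -1)


@dataclass
class AnovaResult:
    table: pd.DataFrame     # index ANOVA_ROWS; columns ss, df, ms, F, p
    denominators: str

    def __getitem__(self, row: str) -> pd.Series:
        return self.table.loc[row]


def anova_selectivity(records: pd.DataFrame, *, denominators: str = "error") -> AnovaResult:
    """Category x hemisphere ANOVA of selectivity with subject as a random
    factor, constrained (Type III) sums of squares.

    ``records`` must hold one method's rows with columns subject,
    category, hemisphere, selectivity, froi; the subject x region crossing
    must be complete. With ``denominators='error'`` every F uses the Error
    mean square; ``'mixed'`` tests each main effect against its
    interaction with subject.
    """
    if denominators not in ("error", "mixed"):
        raise ValueError("denominators must be 'error' or 'mixed'")
    required = {"subject", "category", "hemisphere", "selectivity", "froi"}
    if not required.issubset(records.columns):
        raise ValueError(f"records missing columns: {sorted(required - set(records.columns))}")
    if records["method"].nunique() > 1 if "method" in records.columns else False:
        raise ValueError("pass records for a single method")

    cells = records.groupby(["subject", "froi"], observed=True).size()
    subjects = sorted(records["subject"].unique())
    frois = sorted(records["froi"].unique())
    expected = {(s, f) for s in subjects for f in frois}
    missing = sorted(expected - set(cells.index))
    if missing or (cells > 1).any():
        raise ValueError(f"incomplete subject x region crossing; missing cells: {missing[:10]}")

    y = records["selectivity"].to_numpy(dtype=float)
    N = len(y)
    dom = _sum_code(records["category"].to_numpy(), sorted(records["category"].unique()))
    hem = _sum_code(records["hemisphere"].to_numpy(), sorted(records["hemisphere"].unique()))
    sub = _sum_code(records["subject"].to_numpy(), subjects)

    terms = {
        "Domain": dom,
        "Hemisphere": hem,
        "Subject": sub,
        "Domain*Hemisphere": _interaction(dom, hem),
        "Domain*Subject": _interaction(dom, sub),
        "Hemisphere*Subject": _interaction(hem, sub),
    }

    def sse(mats: list[np.ndarray]) -> float:
        X = np.column_stack([np.ones(N)] + mats)
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(resid @ resid)

    sse_full = sse(list(terms.values()))
    model_df = sum(m.shape[1] for m in terms.values())
    err_df = N - 1 - model_df
    if err_df <= 0:
        raise ValueError("no error degrees of freedom")

    rows = {}
    for name, M in terms.items():
        reduced = [m for t, m in terms.items() if t != name]
        rows[name] = {"ss": max(sse(reduced) - sse_full, 0.0), "df": M.shape[1]}
    rows["Error"] = {"ss": sse_full, "df": err_df}
    rows["Total"] = {"ss": float(((y - y.mean()) ** 2).sum()), "df": N - 1}

    tab = pd.DataFrame(rows).T.reindex(list(ANOVA_ROWS))
    tab["ms"] = tab["ss"] / tab["df"]

    denom_map = {name: "Error" for name in terms}
    if denominators == "mixed":
        denom_map["Domain"] = "Domain*Subject"
        denom_map["Hemisphere"] = "Hemisphere*Subject"

    Fs, ps = {}, {}
    for name in terms:
        dn = denom_map[name]
        F = tab.loc[name, "ms"] / tab.loc[dn, "ms"]
        Fs[name] = F
        ps[name] = float(sps.f.sf(F, tab.loc[name, "df"], tab.loc[dn, "df"]))
    tab["F"] = pd.Series(Fs)
    tab["p"] = pd.Series(ps)
    return AnovaResult(table=tab, denominators=denominators)


@dataclass
class MethodComparison:
    selectivity_tests: pd.DataFrame   # per method x froi: t vs 0
    pairwise: pd.DataFrame            # reference vs other methods per froi
    summary: pd.DataFrame             # per method: n_frois, n_selective
    alpha: float


def compare_methods(
    records: pd.DataFrame,
    *,
    reference: str = "connectivity",
    alpha: float = 0.05,
) -> MethodComparison:
    """Per-region selectivity tests and reference-vs-method paired tests.

    Per-region selectivity uses a Bonferroni threshold of alpha / n_frois;
    pairwise comparisons use alpha / (n_frois * n_method_pairs). Identical
    records across two methods (zero-variance differences) are reported as
    "no difference" rather than erroring.
    """
    methods = sorted(records["method"].unique())
    if reference not in methods:
        raise ValueError(f"reference method {reference!r} absent from records")
    frois = sorted(records["froi"].unique())
    thr_sel = bonferroni_threshold(alpha, len(frois))

    sel_rows = []
    for method in methods:
        sub = records[records["method"] == method]
        if sub.empty:
            logger.warning("method %s has no records; excluded", method)
            continue
        for froi in frois:
            vals = sub.loc[sub["froi"] == froi].sort_values("subject")["selectivity"]
            if len(vals) < 2:
                continue
            try:
                res = one_sample_ttest(vals.to_numpy())
                sel_rows.append(
                    {
                        "method": method, "froi": froi, "t": res.t, "df": res.df,
                        "p": res.p, "mean_selectivity": res.mean_diff, "n": res.n,
                        "selective": bool(res.p < thr_sel and res.mean_diff > 0),
                    }
                )
            except ValueError:
                sel_rows.append(
                    {
                        "method": method, "froi": froi, "t": np.nan, "df": len(vals) - 1,
                        "p": np.nan, "mean_selectivity": float(vals.mean()), "n": len(vals),
                        "selective": False,
                    }
                )
    sel_df = pd.DataFrame(sel_rows)

    others = [m for m in methods if m != reference]
    thr_pair = bonferroni_threshold(alpha, max(len(frois) * len(others), 1))
    pair_rows = []
    ref = records[records["method"] == reference]
    for method in others:
        oth = records[records["method"] == method]
        for froi in frois:
            a = ref.loc[ref["froi"] == froi].sort_values("subject")
            b = oth.loc[oth["froi"] == froi].sort_values("subject")
            common = sorted(set(a["subject"]) & set(b["subject"]))
            if len(common) < 2:
                continue
            av = a.set_index("subject").loc[common, "selectivity"].to_numpy()
            bv = b.set_index("subject").loc[common, "selectivity"].to_numpy()
            row = {
                "froi": froi, "method": method, "reference": reference,
                "mean_diff": float(np.mean(av - bv)), "n": len(common),
            }
            try:
                res = paired_ttest(av, bv)
                row.update(t=res.t, df=res.df, p=res.p,
                           significant=bool(res.p < thr_pair))
            except ValueError:
                row.update(t=np.nan, df=len(common) - 1, p=np.nan, significant=False,
                           note="no difference")
            pair_rows.append(row)
    pair_df = pd.DataFrame(pair_rows)

    summary = (
        sel_df.groupby("method", observed=True)
        .agg(n_frois=("froi", "nunique"), n_selective=("selective", "sum"))
        .reset_index()
    )
    return MethodComparison(
        selectivity_tests=sel_df, pairwise=pair_df, summary=summary, alpha=alpha
    )
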