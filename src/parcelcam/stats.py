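"""Statistical evaluation of parcel relevance values.

Turns per-session RV tables into the explainability outputs: refined
per-class parcel samples, normality-gated two-sample tests with
Benjamini-Yekutieli FDR correction, ranking of the most relevant parcels
(top 15th percentile), derived subsets, and overlap reports against
anatomical target sets.

Refinement applies, in order: (i) drop misclassified sessions, (ii) average
RVs per parcel across a subject's remaining same-class sessions, (iii) drop
subjects still carrying both classes, (iv) separate the AD and HC samples.
Each retained subject then contributes exactly one value per parcel to
exactly one class sample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .atlas import TargetSet

__all__ = [
    "RefinedSets", "RankingResult",
    "refine_rv_sets", "parcelwise_tests", "rank_top_parcels",
    "subset_and_target_report", "benjamini_yekutieli", "calibration_run",
]


@dataclass
class RefinedSets:
    """Per-class RV samples: DataFrames of shape (subjects x parcels)."""

    ad: pd.DataFrame
    hc: pd.DataFrame
    audit: dict = field(default_factory=dict)

    @property
    def parcel_ids(self) -> list[int]:
        return list(self.ad.columns)

    def samples(self, parcel_id: int) -> tuple[np.ndarray, np.ndarray]:
        return (self.ad[parcel_id].to_numpy(), self.hc[parcel_id].to_numpy())


@dataclass
class RankingResult:
    order: dict[str, list[int]]  # per class, parcels by descending mean RV
    top: dict[str, list[int]]
    fraction: float
    statistic: str = "mean"


def refine_rv_sets(rv_table: pd.DataFrame, predictions: pd.DataFrame,
                   session_table: pd.DataFrame | None = None) -> RefinedSets:
    """Apply the four refinement steps; see module docstring.

    ``rv_table`` holds rows (session_id, subject_id, class_label, parcel_id,
    rv) where class_label is the attribution class; the class retained for a
    session is its true class (after step (i) predicted equals true).
    ``predictions`` needs columns session_id, true_label, predicted_label.
    """
    pred = predictions.set_index("session_id")
    n_input_sessions = pred.index.nunique()
    correct = pred[pred["true_label"] == pred["predicted_label"]]
    n_misclassified = n_input_sessions - len(correct)

    t = rv_table[rv_table["session_id"].isin(correct.index)].copy()
    t["true_label"] = correct["true_label"].reindex(t["session_id"]).to_numpy()
    # attribution class = the session's true class
    t = t[t["class_label"] == t["true_label"]]

    # (ii) average per subject within class
    per_subject = (
        t.groupby(["subject_id", "true_label", "parcel_id"])["rv"]
        .mean().reset_index()
    )
    # (iii) drop subjects retaining both classes
    cls_per_subject = per_subject.groupby("subject_id")["true_label"].nunique()
    dual = set(cls_per_subject[cls_per_subject > 1].index)
    n_dual_sessions = int(
        correct.index.isin(
            rv_table.loc[rv_table["subject_id"].isin(dual), "session_id"]
        ).sum()
    )
    per_subject = per_subject[~per_subject["subject_id"].isin(dual)]

    def pivot(lab: str) -> pd.DataFrame:
        sub = per_subject[per_subject["true_label"] == lab]
        return sub.pivot(index="subject_id", columns="parcel_id", values="rv")

    ad, hc = pivot("AD"), pivot("HC")
    if ad.empty or hc.empty:
        empty = "AD" if ad.empty else "HC"
        raise ValueError(f"no {empty} subjects remain after refinement")
    audit = {
        "input_sessions": int(n_input_sessions),
        "removed_misclassified": int(n_misclassified),
        "removed_dual_class_sessions": n_dual_sessions,
        "retained_sessions": int(n_input_sessions - n_misclassified
                                 - n_dual_sessions),
        "retained_subjects": {"AD": len(ad), "HC": len(hc)},
    }
    return RefinedSets(ad=ad, hc=hc, audit=audit)


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    """Kolmogorov-Smirnov check of standardized values against N(0, 1)."""
    sd = x.std(ddof=1)
    if sd == 0:
        return False
    z = (x - x.mean()) / sd
    return sps.kstest(z, "norm").pvalue > alpha


def parcelwise_tests(sets: RefinedSets, alpha: float = 0.05,
                     normality: str = "ks", welch: bool = True) -> pd.DataFrame:
    """Two-sample comparison of AD vs HC RVs per parcel, BY-corrected.

    A parcel uses the t-test only when both samples pass the normality
    check; otherwise the two-sided Mann-Whitney U.  ``normality`` is "ks"
    (standardized KS against the standard normal) or "lilliefors".
    """
    rows = []
    for p in sets.parcel_ids:
        a, h = sets.samples(p)
        if len(a) < 3 or len(h) < 3:
            raise ValueError(f"parcel {p}: need >= 3 values per class sample")
        degenerate = a.std(ddof=1) == 0 or h.std(ddof=1) == 0
        if degenerate:
            warnings.warn(f"parcel {p}: constant sample, using Mann-Whitney",
                          RuntimeWarning, stacklevel=2)
            normal = False
        elif normality == "lilliefors":
            from statsmodels.stats.diagnostic import lilliefors
            normal = (lilliefors(a)[1] > alpha) and (lilliefors(h)[1] > alpha)
        else:
            normal = _is_normal(a, alpha) and _is_normal(h, alpha)
        if normal:
            test = "t"
            pval = sps.ttest_ind(a, h, equal_var=not welch).pvalue
        else:
            test = "mann_whitney"
            if degenerate and np.array_equal(np.unique(a), np.unique(h)) \
                    and len(np.unique(np.concatenate([a, h]))) == 1:
                pval = 1.0
            else:
                pval = sps.mannwhitneyu(a, h, alternative="two-sided").pvalue
        rows.append({
            "parcel_id": p, "test": test, "p_raw": float(pval),
            "direction": "AD" if a.mean() > h.mean() else "HC",
        })
    out = pd.DataFrame(rows).set_index("parcel_id")
    reject, p_adj, _, _ = multipletests(out["p_raw"], alpha=alpha,
                                        method="fdr_by")
    out["p_adj"] = np.minimum(p_adj, 1.0)
    out["significant"] = reject
    return out


def benjamini_yekutieli(pvals: np.ndarray, alpha: float = 0.05):
    """BY step-up adjusted p-values (wraps the statsmodels procedure)."""
    reject, p_adj, _, _ = multipletests(np.asarray(pvals, dtype=float),
                                        alpha=alpha, method="fdr_by")
    return reject, np.minimum(p_adj, 1.0)


def rank_top_parcels(sets: RefinedSets, fraction: float = 0.15,
                     statistic: str = "mean") -> RankingResult:
    """Rank parcels by per-class RV summary; keep the top 15th percentile.

    Top size is ceil(fraction * n_parcels) — 20 of 132.  Ties at the cut
    break by ascending parcel id for determinism.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    n = len(sets.parcel_ids)
    n_top = math.ceil(fraction * n)
    order, top = {}, {}
    for lab, frame in (("AD", sets.ad), ("HC", sets.hc)):
        summary = frame.median(axis=0) if statistic == "median" else frame.mean(axis=0)
        ranked = sorted(summary.index, key=lambda p: (-summary[p], p))
        order[lab] = [int(p) for p in ranked]
        top[lab] = sorted(int(p) for p in ranked[:n_top])
    return RankingResult(order=order, top=top, fraction=fraction,
                         statistic=statistic)


def subset_and_target_report(rank: RankingResult, tests: pd.DataFrame,
                             targets: list[TargetSet],
                             parcel_table: pd.DataFrame | None = None) -> dict:
    """Derived parcel subsets and anatomical-target overlap.

    Per class: top parcels split into significant / non-significant; the
    non-significant ones common to both classes' top sets are reported
    separately (regions driving both classes without favoring one).  Per
    target set: how many of its parcels reach significance, as a count and
    fraction, both per-parcel and with bilateral structures collapsed to one
    unit (requires ``parcel_table`` with name/hemisphere columns).
    """
    significant = set(tests.index[tests["significant"]].astype(int))
    report: dict = {"classes": {}, "targets": {}}
    nonsig_top: dict[str, set[int]] = {}
    for lab, top in rank.top.items():
        tset = set(top)
        report["classes"][lab] = {
            "top": sorted(tset),
            "top_significant": sorted(tset & significant),
            "top_non_significant": sorted(tset - significant),
        }
        nonsig_top[lab] = tset - significant
    if len(nonsig_top) == 2:
        common = set.intersection(*nonsig_top.values())
        report["common_non_significant"] = sorted(common)

    for t in targets:
        ids = set(int(p) for p in t.parcel_ids)
        sig_in_target = ids & significant
        entry = {
            "n_parcels": len(ids),
            "n_significant": len(sig_in_target),
            "fraction_significant": len(sig_in_target) / len(ids) if ids else 0.0,
            "direction_counts": tests.loc[sorted(sig_in_target), "direction"]
            .value_counts().to_dict() if sig_in_target else {},
        }
        if parcel_table is not None:
            sub = parcel_table[parcel_table["parcel_id"].isin(ids)]
            units = sub.groupby("name")["parcel_id"].apply(set)
            n_units = len(units)
            n_sig_units = int(sum(bool(u & sig_in_target) for u in units))
            entry["n_units_collapsed"] = n_units
            entry["n_significant_units_collapsed"] = n_sig_units
            entry["fraction_significant_collapsed"] = (
                n_sig_units / n_units if n_units else 0.0
            )
        report["targets"][t.name] = entry
    return report


def calibration_run(n_replicates: int = 200, n_parcels: int = 132,
                    n_per_class: int = 50, shift: float = 0.0,
                    n_shifted: int = 1, alpha: float = 0.05,
                    seed: int = 0) -> dict:
    """Monte-Carlo calibration of the parcel-wise testing stage.

    Each replicate draws both class samples i.i.d. from the standard normal
    for every parcel and runs the full normality-gated, BY-corrected testing
    procedure.  With ``shift`` > 0, the AD sample of the first ``n_shifted``
    parcels is shifted by that many pooled SDs, and the detection rate of
    those parcels is reported as ``power``; the false-positive fraction is
    always measured on the unshifted parcels.
    """
    rng = np.random.default_rng(seed)
    null_flags, shifted_flags = [], []
    for _ in range(n_replicates):
        ad = rng.standard_normal((n_per_class, n_parcels))
        hc = rng.standard_normal((n_per_class, n_parcels))
        if shift > 0:
            ad[:, :n_shifted] += shift
        parcels = list(range(1, n_parcels + 1))
        sets = RefinedSets(ad=pd.DataFrame(ad, columns=parcels),
                           hc=pd.DataFrame(hc, columns=parcels))
        res = parcelwise_tests(sets, alpha=alpha)
        sig = res["significant"].to_numpy()
        null_flags.append(sig[n_shifted:] if shift > 0 else sig)
        if shift > 0:
            shifted_flags.append(sig[:n_shifted])
    out = {
        "fraction_significant_null": float(np.concatenate(null_flags).mean()),
        "n_replicates": n_replicates,
    }
    if shift > 0:
        out["power"] = float(np.concatenate(shifted_flags).mean())
    return out
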