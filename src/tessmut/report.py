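"""Structure–function summary statistics.

Reproduces the descriptive analyses that sit between the raw
computational-mutagenesis scores and the predictive models: mean
residual scores by activity category, the RES/CMP quadrant layout,
chi-square contingency tests, the CMP-on-RES regression, and summaries
over annotated residue groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import ActivityRecord
from .mutagenesis import substitution_class

#: Default residue polarity classes (configurable; the exact assignment
#: behind published margins is not standardized).
POLARITY_CLASSES = {
    "charged": frozenset("DEKRH"),
    "polar": frozenset("STNQCY"),
    "apolar": frozenset("AVLIMFWPG"),
}


class ReportError(ValueError):
    """Raised for inconsistent report inputs."""


def polarity(residue: str,
             classes: dict[str, frozenset] = POLARITY_CLASSES) -> str:
    for name, members in classes.items():
        if residue in members:
            return name
    raise ReportError(f"residue {residue!r} not covered by polarity classes")


def category_means(records: list[ActivityRecord],
                   residuals: dict[str, float]) -> pd.DataFrame:
    """Mean residual score per (activity category × substitution class).

    Rows: Superior / Similar / Inferior; columns All, C, NC with means
    and counts, plus pairwise two-sample t-test p-values between
    categories on the All residuals.
    """
    rows = []
    for record in records:
        key = str(record.variant)
        if key not in residuals:
            raise ReportError(f"no residual score for variant {key}")
        rows.append({
            "variant": key,
            "category3": record.category3,
            "sub_class": substitution_class(record.variant.native,
                                            record.variant.replacement),
            "residual": residuals[key],
        })
    frame = pd.DataFrame(rows)
    out_rows = []
    for category in ("Superior", "Similar", "Inferior"):
        sub = frame[frame.category3 == category]
        row = {"category": category}
        for label, mask in (("All", np.ones(len(sub), dtype=bool)),
                            ("C", (sub.sub_class == "C").to_numpy()),
                            ("NC", (sub.sub_class == "NC").to_numpy())):
            values = sub.residual.to_numpy()[mask]
            row[f"{label}_mean"] = float(np.mean(values)) if len(values) else float("nan")
            row[f"{label}_n"] = int(len(values))
        out_rows.append(row)
    table = pd.DataFrame(out_rows).set_index("category")

    pvals = {}
    for a, b in (("Superior", "Similar"), ("Similar", "Inferior"),
                 ("Superior", "Inferior")):
        va = frame[frame.category3 == a].residual
        vb = frame[frame.category3 == b].residual
        if len(va) > 1 and len(vb) > 1:
            pvals[f"{a}/{b}"] = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
        else:
            pvals[f"{a}/{b}"] = float("nan")
    table.attrs["t_test_p"] = pvals
    return table


def quadrant_assignment(res: float, cmp_score: float) -> str:
    """Quadrant of a (RES, CMP) point; zeros go to the positive side."""
    if res >= 0 and cmp_score >= 0:
        return "Q1"
    if res < 0 and cmp_score >= 0:
        return "Q2"
    if res < 0 and cmp_score < 0:
        return "Q3"
    return "Q4"


def quadrant_table(res: np.ndarray, cmp_scores: np.ndarray,
                   residue_types: str | list[str]) -> pd.DataFrame:
    """Quadrant × polarity contingency counts over structure positions."""
    res = np.asarray(res, dtype=float)
    cmp_scores = np.asarray(cmp_scores, dtype=float)
    if len(res) != len(cmp_scores) or len(res) != len(residue_types):
        raise ReportError("RES, CMP and residue types must align")
    counts = pd.DataFrame(0, index=["Q1", "Q2", "Q3", "Q4"],
                          columns=list(POLARITY_CLASSES))
    for r, c, aa in zip(res, cmp_scores, residue_types):
        counts.loc[quadrant_assignment(r, c), polarity(aa)] += 1
    return counts


def contingency_chi_square(table: pd.DataFrame | np.ndarray) -> tuple[float, int]:
    """Pearson chi-square with df = (r−1)(c−1); no continuity correction."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ReportError("contingency table needs >= 2 rows and >= 2 columns")
    if (counts < 0).any():
        raise ReportError("negative counts in contingency table")
    if counts.sum() == 0:
        raise ReportError("empty contingency table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ReportError("zero row or column margin")
    result = stats.chi2_contingency(counts, correction=False)
    return float(result.statistic), int(result.dof)


def fisher_exact_rxc(table: pd.DataFrame | np.ndarray,
                     n_resamples: int = 20_000, seed: int = 0) -> float:
    """Fisher-style exact/Monte-Carlo p for an r×c table (reported alongside chi2)."""
    counts = np.asarray(table, dtype=int)
    if counts.shape == (2, 2):
        return float(stats.fisher_exact(counts)[1])
    res = stats.chi2_contingency(counts, correction=False)
    rng = np.random.default_rng(seed)
    row_margins = counts.sum(axis=1)
    col_margins = counts.sum(axis=0)
    observed = res.statistic
    hits = 0
    for _ in range(n_resamples):
        sim = stats.random_table.rvs(row_margins, col_margins, random_state=rng)
        stat = stats.chi2_contingency(sim, correction=False).statistic
        if stat >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_resamples + 1)


def cmp_res_correlation(res: np.ndarray, cmp_scores: np.ndarray
                        ) -> tuple[float, float, float]:
    """OLS of CMP on RES: (slope, intercept, R²).  NaN pairs are dropped."""
    res = np.asarray(res, dtype=float)
    cmp_scores = np.asarray(cmp_scores, dtype=float)
    if len(res) != len(cmp_scores) or len(res) < 3:
        raise ReportError("need aligned vectors of length >= 3")
    mask = np.isfinite(res) & np.isfinite(cmp_scores)
    res, cmp_scores = res[mask], cmp_scores[mask]
    if np.std(res) == 0:
        raise ReportError("zero variance in RES")
    fit = stats.linregress(res, cmp_scores)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)


@dataclass
class GroupSummary:
    """Aggregate scores for a named group of residue positions."""

    name: str
    positions: list[int]
    mres: float          # mean residue environment score over the group
    all_mean: float      # mean residual over all 19×N substitutions
    c_mean: float
    nc_mean: float
    n_all: int
    n_c: int
    n_nc: int


def annotated_group_summary(groups: dict[str, list[int]],
                            res_by_position: dict[int, float],
                            residuals: pd.DataFrame) -> list[GroupSummary]:
    """Per-group M.R.E.S. and All/C/NC mean residual scores.

    ``residuals`` must have columns ``position``, ``native``,
    ``replacement``, ``residual`` — one row per substitution (19 per
    position for a complete scan).
    """
    required = {"position", "native", "replacement", "residual"}
    if not required <= set(residuals.columns):
        raise ReportError(f"residuals table needs columns {sorted(required)}")
    summaries = []
    for name, positions in groups.items():
        for pos in positions:
            if pos not in res_by_position:
                raise ReportError(f"group {name!r}: unknown position {pos}")
        sub = residuals[residuals.position.isin(positions)]
        classes = sub.apply(lambda r: substitution_class(r["native"], r["replacement"]),
                            axis=1) if len(sub) else pd.Series(dtype=object)
        c_vals = sub.residual[classes == "C"] if len(sub) else pd.Series(dtype=float)
        nc_vals = sub.residual[classes == "NC"] if len(sub) else pd.Series(dtype=float)
        summaries.append(GroupSummary(
            name=name, positions=list(positions),
            mres=float(np.mean([res_by_position[p] for p in positions])),
            all_mean=float(sub.residual.mean()) if len(sub) else float("nan"),
            c_mean=float(c_vals.mean()) if len(c_vals) else float("nan"),
            nc_mean=float(nc_vals.mean()) if len(nc_vals) else float("nan"),
            n_all=int(len(sub)), n_c=int(len(c_vals)), n_nc=int(len(nc_vals)),
        ))
    return summaries


#: Annotated Gal4 residue groups (author numbering, chain A of 3coq).
GAL4_GROUPS = {
    "binuclear_cluster": [11, 14, 21, 28, 31, 38],
    "linker": [41, 42, 43, 44, 45, 46, 47, 48, 49],
    "interface_core": [60, 63, 64, 67, 68, 70, 71, 72, 77, 80, 81, 83, 89, 92, 93],
    "conserved_core": [67, 71, 80, 81, 93],
}
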