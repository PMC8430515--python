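"""Diagnostic pathway classification and PCA-based taxonomy refinement.

Patients are grouped by the earliest pathway-initiating milestone in their
lookback history: a FIT (``screening``), a primary-care blood test
(``blood_test``), or a symptom/bowel-obstruction diagnosis (``symptom``).
Histories containing only procedures (colonoscopy, surgery, CT) carry no
initiator and are ``unclassified``. Same-day ties resolve by the fixed
priority fit > blood_test > symptom.

PCA on the per-patient milestone count matrix (Kaiser criterion, varimax
then promax rotation) is provided as a diagnostic for which milestones
cluster together; the group assignment itself is rule-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

from .registry import CATEGORIES, SYMPTOM_CATEGORIES

INITIATOR_GROUPS: dict[str, str] = {"fit": "screening", "blood_test": "blood_test",
                                    **{c: "symptom" for c in SYMPTOM_CATEGORIES}}

#: Same-day tie priority among initiating categories (lower = wins).
_PRIORITY = {"fit": 0, "blood_test": 1, **{c: 2 for c in SYMPTOM_CATEGORIES}}

#: Expected milestone order per group, used by the chronology check.
GROUP_TEMPLATES: dict[str, tuple[str, ...]] = {
    "screening": ("fit", "colonoscopy", "surgery"),
    "blood_test": ("blood_test", "colonoscopy", "surgery"),
    "symptom": ("symptom", "colonoscopy", "surgery"),
}


def count_milestones(linked: pd.DataFrame,
                     patient_ids: pd.Series | None = None) -> pd.DataFrame:
    """Per-patient milestone counts within the lookback window.

    Returns a patients x categories table of nonnegative integers indexed by
    ``patient_id`` (all categories present as columns; patients without
    events, if ``patient_ids`` is given, appear with all-zero rows).
    """
    counts = (linked.groupby(["patient_id", "category"], observed=True)
              .size().unstack(fill_value=0))
    counts = counts.reindex(columns=list(CATEGORIES), fill_value=0)
    if patient_ids is not None:
        counts = counts.reindex(pd.Index(patient_ids, name="patient_id"), fill_value=0)
    return counts.astype(int)


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray          # all eigenvalues, descending
    n_retained: int                  # Kaiser criterion: eigenvalue >= 1
    loadings: pd.DataFrame           # promax-rotated, milestones x components
    rotation: str = "promax"

    @property
    def retained_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[: self.n_retained]


def _promax(A: np.ndarray, power: int) -> np.ndarray:
    """Promax: oblique procrustes rotation of varimax loadings toward the
    element-wise power target sign(v)|v|^power (zero loadings map to a zero
    target, which keeps perfectly block-structured inputs well defined)."""
    V, _T = rotate_factors(A, "varimax")
    H = np.where(V == 0.0, 0.0, np.sign(V) * np.abs(V) ** power)
    S = np.linalg.solve(A.T @ A, A.T @ H)
    d = np.sqrt(np.diag(np.linalg.inv(S.T @ S)))
    T = np.linalg.inv(S @ np.diag(d)).T
    return A @ T


def pca_refine(count_matrix: pd.DataFrame, promax_power: int = 4) -> PCAResult:
    """PCA of the standardized milestone count matrix.

    Columns are standardized; the correlation matrix is eigendecomposed;
    components with eigenvalue >= 1 are retained (Kaiser); loadings are
    varimax- then promax-rotated (oblique). Constant columns are dropped
    with a warning. Raises if fewer than two usable columns remain.
    """
    X = count_matrix.to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if (~keep).any():
        import logging
        logging.getLogger(__name__).warning(
            "dropping %d constant milestone columns from PCA", int((~keep).sum()))
    names = [c for c, k in zip(count_matrix.columns, keep) if k]
    if len(names) < 2:
        raise ValueError("PCA requires at least two milestones with nonzero variance")
    corr = np.corrcoef(X[:, keep], rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_retained = int((eigvals >= 1.0).sum())
    k = max(n_retained, 1)
    load = eigvecs[:, :k] * np.sqrt(np.maximum(eigvals[:k], 0.0))
    if k >= 2:
        load = _promax(load, promax_power)
    loadings = pd.DataFrame(load, index=pd.Index(names, name="milestone"),
                            columns=[f"PC{i + 1}" for i in range(k)])
    return PCAResult(eigenvalues=eigvals, n_retained=n_retained, loadings=loadings)


def assign_pathway(linked: pd.DataFrame, patient_ids=None) -> pd.DataFrame:
    """Classify each patient's pathway from the earliest initiating event.

    Returns one row per patient: ``patient_id``, ``group``,
    ``initiating_category`` / ``initiating_date`` (missing when
    unclassified) and ``detail`` — the ordered sequence of distinct
    milestone categories observed (first occurrences, '>'-joined).
    A pure function of the history: row order of the input is irrelevant.
    """
    ev = linked.sort_values(["patient_id", "event_date", "category"],
                            kind="mergesort")
    # detail string: first occurrence of each category in time order
    firsts = ev.drop_duplicates(["patient_id", "category"])
    detail = (firsts.groupby("patient_id", observed=True)["category"]
              .agg(">".join).rename("detail"))

    inits = ev[ev["category"].isin(INITIATOR_GROUPS)].copy()
    inits["prio"] = inits["category"].map(_PRIORITY)
    inits = inits.sort_values(["patient_id", "event_date", "prio"], kind="mergesort")
    first_init = inits.drop_duplicates("patient_id")[
        ["patient_id", "category", "event_date"]]
    first_init = first_init.rename(columns={"category": "initiating_category",
                                            "event_date": "initiating_date"})
    first_init["group"] = first_init["initiating_category"].map(INITIATOR_GROUPS)

    if patient_ids is None:
        patient_ids = ev["patient_id"].unique()
    out = pd.DataFrame({"patient_id": pd.Index(patient_ids)})
    out = out.merge(detail, on="patient_id", how="left").merge(
        first_init, on="patient_id", how="left")
    out["group"] = out["group"].fillna("unclassified")
    out["detail"] = out["detail"].fillna("")
    return out


def pathway_proportions(assignments: pd.DataFrame) -> tuple[pd.Series, float]:
    """Group shares among classified patients, plus the classified fraction.

    Raises if no patient is classified.
    """
    n = len(assignments)
    classified = assignments.loc[assignments["group"] != "unclassified"]
    if classified.empty:
        raise ValueError("no classified patients")
    props = (classified["group"].value_counts(normalize=True)
             .reindex(["screening", "blood_test", "symptom"], fill_value=0.0))
    return props, len(classified) / n


def validate_chronology(linked: pd.DataFrame, assignments: pd.DataFrame) -> float:
    """Fraction of template milestone-pair gaps that are nonnegative.

    For each classified patient, the first occurrence of each milestone in
    the group's expected template is taken; consecutive differences (days)
    between those present are pooled across patients, and the fraction >= 0
    is returned — 1.0 means every observed history respects the hypothesized
    chronological order.
    """
    ev = linked.copy()
    ev["tmpl_cat"] = np.where(ev["category"].isin(SYMPTOM_CATEGORIES),
                              "symptom", ev["category"])
    firsts = (ev.sort_values(["patient_id", "event_date"], kind="mergesort")
              .drop_duplicates(["patient_id", "tmpl_cat"])
              .set_index(["patient_id", "tmpl_cat"])["event_date"])
    n_ok = 0
    n_total = 0
    grouped = assignments.loc[assignments["group"] != "unclassified",
                              ["patient_id", "group"]]
    for pid_, group in grouped.itertuples(index=False):
        template = GROUP_TEMPLATES[group]
        dates = [firsts.get((pid_, cat)) for cat in template]
        dates = [d for d in dates if d is not None and not pd.isna(d)]
        for a, b in zip(dates, dates[1:]):
            n_total += 1
            n_ok += (b - a).days >= 0
    return 1.0 if n_total == 0 else n_ok / n_total
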