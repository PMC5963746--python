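"""Procrustes ANOVA: variance partitioning for size and shape, R2 and ICC.

For centroid size the partitions are classical univariate ANOVAs.  For shape
the sums of squares are accumulated jointly over all Procrustes coordinates
and the classical degrees of freedom are multiplied by the shape-space
dimension 3p - 7 (p landmarks in 3D: 3p coordinates minus 3 translations,
3 rotations and 1 scale), the convention under which a 20-individual,
3-replicate, 15-landmark design has individual df (20-1)*38 = 722 and error
df 20*2*38 = 1520.  F ratios are referred to the F distribution on those
inflated df (Goodall-style); seeded permutation P values are available as a
distribution-free alternative.

Three designs are covered:

* ``repeatability_anova`` — individuals vs replicate error (balanced k >= 2),
  with R2 per effect and the intraclass correlation from the mean squares;
* ``grouping_anova`` — a one-way partition by an arbitrary grouping factor
  (operators), whose group R2 approximates the inter-operator bias share;
* ``hierarchical_anova`` — sequential (Type I) partition with sex entered
  before operator, so the operator share is the sex-adjusted remainder.

The default ICC is the symmetric mean-squares form
``(MS_among - MS_within) / (MS_among + MS_within)``; the classical one-way
variant is available via ``variant="one_way"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import LandmarkDataset
from .procrustes import ProcrustesFit, gpa_align

ANOVA_COLUMNS = ["effect", "SS", "df", "MS", "F", "P", "R2"]


@dataclass
class AnovaTable:
    """Effect rows (SS, df, MS, F, P, R2 in percent) plus totals.

    Invariants checked on construction: SS additivity, df bookkeeping,
    MS = SS/df, and R2 summing to 100%.
    """

    trait: str  # "size" | "shape"
    rows: pd.DataFrame
    shape_dim: int
    subset: str | None = None
    k_replicates: int | None = None

    def __post_init__(self) -> None:
        r = self.rows
        if list(r.columns) != ANOVA_COLUMNS:
            raise ValueError(f"rows must have columns {ANOVA_COLUMNS}")
        if (r["SS"] < -1e-12).any():
            raise ValueError("negative sum of squares")
        ss_total = float(r["SS"].sum())
        if ss_total > 0:
            recomputed = r["SS"] / r["df"]
            if not np.allclose(recomputed, r["MS"], rtol=1e-9):
                raise ValueError("MS != SS/df")
            if not np.isclose(r["R2"].sum(), 100.0, atol=1e-6):
                raise ValueError("R2 does not sum to 100%")
            if not np.allclose(r["R2"], 100.0 * r["SS"] / ss_total, atol=1e-9):
                raise ValueError("R2 inconsistent with SS")

    @property
    def ss_total(self) -> float:
        return float(self.rows["SS"].sum())

    @property
    def df_total(self) -> int:
        return int(self.rows["df"].sum())

    def r2(self, effect: str) -> float:
        """Unrounded R2 (percent) of one effect."""
        sel = self.rows.loc[self.rows["effect"] == effect, "R2"]
        if sel.empty:
            raise KeyError(f"no effect {effect!r} in table")
        return float(sel.iloc[0])

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "subset": self.subset,
            "shape_dim": self.shape_dim,
            "k_replicates": self.k_replicates,
            "ss_total": self.ss_total,
            "df_total": self.df_total,
            "rows": self.rows.to_dict(orient="records"),
        }


@dataclass
class IccResult:
    """Intraclass correlation from an ANOVA mean-square pair."""

    icc: float
    ms_among: float
    ms_within: float
    variant: str

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "ms_among": self.ms_among,
            "ms_within": self.ms_within,
            "variant": self.variant,
        }


def r2_from_ss(ss_effect: float, ss_total: float) -> float:
    """Percent of total sum of squares accounted for by one effect."""
    if ss_total <= 0:
        raise ValueError("ss_total must be > 0")
    if not 0 <= ss_effect <= ss_total * (1 + 1e-12):
        raise ValueError("need 0 <= ss_effect <= ss_total")
    return 100.0 * ss_effect / ss_total


def icc_from_ms(
    ms_among: float, ms_within: float, variant: str = "symmetric", k: int | None = None
) -> IccResult:
    """ICC from the among/within mean squares of a repeatability ANOVA.

    ``symmetric`` (default): (MSa - MSw)/(MSa + MSw) — the form that
    reproduces published repeatability tables computed this way.
    ``one_way``: the classical one-way variant (MSa - MSw)/(MSa + (k-1) MSw),
    requiring the replicate count k.
    """
    if ms_among < 0 or ms_within < 0:
        raise ValueError("mean squares must be >= 0")
    if ms_among == 0 and ms_within == 0:
        raise ValueError("both mean squares are zero; ICC undefined")
    if variant == "symmetric":
        icc = (ms_among - ms_within) / (ms_among + ms_within)
    elif variant == "one_way":
        if k is None or k < 2:
            raise ValueError("one_way variant requires replicate count k >= 2")
        icc = (ms_among - ms_within) / (ms_among + (k - 1) * ms_within)
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")
    return IccResult(
        icc=float(icc), ms_among=float(ms_among), ms_within=float(ms_within),
        variant=variant,
    )


def _as_response(
    fit_or_values: ProcrustesFit | np.ndarray, trait: str
) -> tuple[np.ndarray, int]:
    """Return (response matrix (n, q), shape_dim multiplier)."""
    if trait == "size":
        y = np.asarray(fit_or_values, dtype=float).reshape(-1, 1)
        return y, 1
    if trait != "shape":
        raise ValueError("trait must be 'size' or 'shape'")
    if isinstance(fit_or_values, ProcrustesFit):
        return fit_or_values.flattened(), fit_or_values.shape_dim
    arr = np.asarray(fit_or_values, dtype=float)
    if arr.ndim == 3:
        p = arr.shape[1]
        return arr.reshape(arr.shape[0], -1), 3 * p - 7
    if arr.ndim == 2:
        # already-flattened coordinates: caller supplies the shape dimension
        raise ValueError(
            "pass a ProcrustesFit or an (n, p, 3) array for trait='shape', "
            "or use shape_dim explicitly via the *_anova(..., shape_dim=) APIs"
        )
    raise ValueError("unrecognized shape input")


def _resolve(
    fit_or_values, trait: str, shape_dim: int | None
) -> tuple[np.ndarray, int]:
    if shape_dim is not None:
        if isinstance(fit_or_values, ProcrustesFit):
            y = fit_or_values.flattened()
        else:
            y = np.asarray(fit_or_values, dtype=float)
            if y.ndim == 3:
                y = y.reshape(y.shape[0], -1)
            elif y.ndim == 1:
                y = y.reshape(-1, 1)
        return y, shape_dim
    return _as_response(fit_or_values, trait)


def _between_within_ss(y: np.ndarray, labels: np.ndarray) -> tuple[float, float, int]:
    """(between-group SS, within-group SS, number of groups) over all columns."""
    grand = y.mean(axis=0)
    ss_b = 0.0
    ss_w = 0.0
    groups = pd.unique(labels)
    for g in groups:
        block = y[labels == g]
        m = block.mean(axis=0)
        ss_b += len(block) * float(((m - grand) ** 2).sum())
        ss_w += float(((block - m) ** 2).sum())
    return ss_b, ss_w, len(groups)


def _build_table(
    trait: str,
    effects: list[tuple[str, float, int]],
    ss_resid: float,
    df_resid: int,
    shape_dim: int,
    subset: str | None = None,
    k_replicates: int | None = None,
    p_values: dict[str, float] | None = None,
) -> AnovaTable:
    ss_total = sum(ss for _, ss, _ in effects) + ss_resid
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan
    rows = []
    for name, ss, df in effects:
        ms = ss / df
        f = ms / ms_resid if ms_resid > 0 else np.inf
        if p_values and name in p_values:
            p = p_values[name]
        elif np.isfinite(f) and df_resid > 0:
            p = float(stats.f.sf(f, df, df_resid))
        else:
            p = 0.0 if ss > 0 else np.nan
        r2 = 100.0 * ss / ss_total if ss_total > 0 else 0.0
        rows.append((name, ss, df, ms, f, p, r2))
    r2_resid = 100.0 * ss_resid / ss_total if ss_total > 0 else 100.0
    rows.append(("residual", ss_resid, df_resid, ms_resid, np.nan, np.nan, r2_resid))
    return AnovaTable(
        trait=trait,
        rows=pd.DataFrame(rows, columns=ANOVA_COLUMNS),
        shape_dim=shape_dim,
        subset=subset,
        k_replicates=k_replicates,
    )


def repeatability_anova(
    fit_or_cs: ProcrustesFit | np.ndarray,
    individual_ids: np.ndarray | list | None = None,
    trait: str = "shape",
    shape_dim: int | None = None,
    icc_variant: str = "symmetric",
    n_permutations: int = 0,
    seed: int = 0,
    subset: str | None = None,
) -> tuple[AnovaTable, IccResult]:
    """Individuals-vs-replicate-error partition of size or shape.

    Requires a balanced design (every individual has the same number k >= 2
    of replicas).  For shape, SS are summed over all aligned coordinates and
    classical df are multiplied by 3p - 7.  The optional permutation P value
    permutes records freely across individuals (the no-individual-differences
    null); the parametric Goodall-style P is always reported in the table.
    """
    if individual_ids is None:
        if not isinstance(fit_or_cs, ProcrustesFit):
            raise ValueError("individual_ids required unless a ProcrustesFit is given")
        individual_ids = fit_or_cs.meta["individual_id"].to_numpy()
    ids = np.asarray(individual_ids)
    y, dim = _resolve(fit_or_cs, trait, shape_dim)
    if len(ids) != y.shape[0]:
        raise ValueError("individual_ids length does not match data")
    counts = pd.Series(ids).value_counts()
    if counts.nunique() != 1 or counts.iloc[0] < 2:
        raise ValueError(
            "repeatability ANOVA requires a balanced design with k >= 2 "
            f"replicas per individual; got counts {sorted(set(counts))}"
        )
    k = int(counts.iloc[0])
    n_ind = len(counts)
    ss_ind, ss_err, _ = _between_within_ss(y, ids)
    df_ind = (n_ind - 1) * dim
    df_err = n_ind * (k - 1) * dim

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        f_obs = (ss_ind / df_ind) / (ss_err / df_err) if ss_err > 0 else np.inf
        hits = 0
        perm_ids = ids.copy()
        for _ in range(n_permutations):
            rng.shuffle(perm_ids)
            sb, sw, _ = _between_within_ss(y, perm_ids)
            f_p = (sb / df_ind) / (sw / df_err) if sw > 0 else np.inf
            hits += f_p >= f_obs
        p_perm = (1 + hits) / (1 + n_permutations)

    table = _build_table(
        trait,
        [("individual", ss_ind, df_ind)],
        ss_err,
        df_err,
        dim,
        subset=subset,
        k_replicates=k,
    )
    if p_perm is not None:
        table.rows.attrs["p_permutation"] = {"individual": p_perm}
    icc = icc_from_ms(
        ss_ind / df_ind, ss_err / df_err, variant=icc_variant, k=k
    )
    return table, icc


def grouping_anova(
    fit_or_cs: ProcrustesFit | np.ndarray,
    group_labels: np.ndarray | list,
    trait: str = "shape",
    shape_dim: int | None = None,
    effect_name: str = "operator",
    n_permutations: int = 0,
    seed: int = 0,
    subset: str | None = None,
) -> AnovaTable:
    """One-way between/within partition by an arbitrary grouping factor.

    The group R2 approximates the share of variance attributable to
    systematic differences among the groups (e.g. operator bias).
    """
    labels = np.asarray(group_labels)
    y, dim = _resolve(fit_or_cs, trait, shape_dim)
    if len(labels) != y.shape[0]:
        raise ValueError("group_labels length does not match data")
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValueError("need >= 2 groups")
    if n_permutations > 0 and trait == "shape" and (counts == 1).any():
        raise ValueError("singleton group: shape permutation test not meaningful")
    n = y.shape[0]
    ss_b, ss_w, g = _between_within_ss(y, labels)
    df_b = (g - 1) * dim
    df_w = (n - g) * dim

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        perm = labels.copy()
        for _ in range(n_permutations):
            rng.shuffle(perm)
            sb, _, _ = _between_within_ss(y, perm)
            hits += sb >= ss_b
        p_perm = (1 + hits) / (1 + n_permutations)

    table = _build_table(
        trait, [(effect_name, ss_b, df_b)], ss_w, df_w, dim, subset=subset
    )
    if p_perm is not None:
        table.rows.attrs["p_permutation"] = {effect_name: p_perm}
    return table


def _dummies(labels: np.ndarray) -> np.ndarray:
    levels = pd.unique(labels)
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]])


def _explained_ss(x: np.ndarray, y: np.ndarray) -> float:
    """SS of Y explained by the column space of X (including intercept)."""
    q, _ = np.linalg.qr(x)
    proj = q.T @ y
    return float((proj**2).sum())


def hierarchical_anova(
    fit_or_cs: ProcrustesFit | np.ndarray,
    sex_labels: np.ndarray | list,
    operator_labels: np.ndarray | list,
    trait: str = "shape",
    shape_dim: int | None = None,
    subset: str | None = None,
) -> AnovaTable:
    """Sequential (Type I) partition: sex first, then sex-adjusted operator.

    Both factors are crossed (every operator may measure both sexes).  The
    operator SS is the increment over the sex-only model, so the operator R2
    is unrelated to — controlled for — sex.  An empty sex-by-operator cell
    triggers a warning but the sequential decomposition still proceeds.
    """
    sex = np.asarray(sex_labels)
    op = np.asarray(operator_labels)
    y, dim = _resolve(fit_or_cs, trait, shape_dim)
    n = y.shape[0]
    if len(sex) != n or len(op) != n:
        raise ValueError("label lengths do not match data")
    if len(pd.unique(sex)) < 2 and len(pd.unique(op)) < 2:
        raise ValueError("both factors are constant")
    cells = pd.crosstab(pd.Series(sex), pd.Series(op))
    if (cells == 0).any().any():
        warnings.warn("empty sex x operator cell; sequential SS still computed")

    yc = y - y.mean(axis=0)
    ss_total = float((yc**2).sum())
    ones = np.ones((n, 1))
    x_sex = np.hstack([ones, _dummies(sex)]) if len(pd.unique(sex)) > 1 else ones
    x_full = (
        np.hstack([x_sex, _dummies(op)]) if len(pd.unique(op)) > 1 else x_sex
    )
    e_sex = _explained_ss(x_sex, yc)
    e_full = _explained_ss(x_full, yc)
    ss_sex = max(e_sex, 0.0)
    ss_op = max(e_full - e_sex, 0.0)
    ss_resid = max(ss_total - e_full, 0.0)

    df_sex = (len(pd.unique(sex)) - 1) * dim
    df_op = (len(pd.unique(op)) - 1) * dim
    df_resid = (n - len(pd.unique(sex)) - len(pd.unique(op)) + 1) * dim
    effects = []
    if df_sex > 0:
        effects.append(("sex", ss_sex, df_sex))
    if df_op > 0:
        effects.append(("operator", ss_op, df_op))
    return _build_table(trait, effects, ss_resid, df_resid, dim, subset=subset)


def balanced_subsample_r2(
    dataset: LandmarkDataset,
    n_per_cell: int,
    seed: int,
    trait: str = "shape",
) -> tuple[AnovaTable, tuple[str, ...]]:
    """Hierarchical ANOVA on a seeded, per-cell-balanced subsample.

    Draws ``n_per_cell`` individuals uniformly without replacement from every
    sex-by-operator cell of a partition-design dataset, then re-runs the
    sequential sex -> operator partition on the subsample (re-superimposing
    for shape).  Returns the table and the sampled individual ids.
    """
    meta = dataset.meta()
    if meta["individual_id"].duplicated().any():
        raise ValueError("balanced subsampling expects one record per individual")
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for (sex, op), grp in sorted(
        meta.groupby(["sex", "operator_id"]), key=lambda kv: kv[0]
    ):
        ids = sorted(grp["individual_id"])
        if len(ids) < n_per_cell:
            raise ValueError(
                f"cell (sex={sex}, operator={op}) has only {len(ids)} "
                f"individuals; {n_per_cell} requested"
            )
        chosen.extend(rng.choice(ids, size=n_per_cell, replace=False))
    keep = set(chosen)
    sub = dataset.filter(lambda r: r.individual_id in keep)
    sub_meta = sub.meta()
    if trait == "shape":
        fit = gpa_align(sub)
        values: ProcrustesFit | np.ndarray = fit
    else:
        from .procrustes import centroid_size

        values = np.array([centroid_size(r.coords) for r in sub.records])
    table = hierarchical_anova(
        values, sub_meta["sex"].to_numpy(), sub_meta["operator_id"].to_numpy(),
        trait=trait,
    )
    return table, tuple(sorted(keep))
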