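"""Full-study reports chaining the analysis stages I -> II -> III.

``run_replica_analysis`` covers a full-replica dataset (every operator
digitized every individual): absolute error profiles, repeatability ANOVAs
with R2/ICC, operator-grouping ANOVAs, size/shape concordance diagnostics
and the UPGMA replica phenogram, on each of the three landmark subsets
(all / bone / nose).  ``run_study_analysis`` covers a partition-design
dataset: hierarchical sex-above-operator ANOVAs, shape PCA exports and the
optional balanced per-cell subsample check.  Reports are plain nested dicts
(JSON-serializable, byte-deterministic for identical inputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from importlib.metadata import PackageNotFoundError, version as _pkg_version

import numpy as np
import pandas as pd

from . import abserr, anova, concordance, ordination
from .io import LandmarkDataset
from .procrustes import centroid_size, distance_to_mean, gpa_align, shape_distance_matrix

log = logging.getLogger("morphoerror")

SUBSETS = ("all", "bone", "nose")


def _version() -> str:
    try:
        return _pkg_version("morphoerror")
    except PackageNotFoundError:
        return "unknown"


def dataset_hash(dataset: LandmarkDataset) -> str:
    h = hashlib.sha256()
    for r in dataset.records:
        h.update("|".join(r.key).encode())
        h.update(np.ascontiguousarray(r.coords, dtype=float).tobytes())
    return h.hexdigest()


def detect_design(dataset: LandmarkDataset) -> str:
    """'replica' if every individual was digitized by every operator once,
    'study' if each individual has exactly one record, else 'mixed'."""
    meta = dataset.meta()
    per_ind = meta.groupby("individual_id")["operator_id"].agg(["nunique", "count"])
    ops = meta["operator_id"].nunique()
    if (per_ind["count"] == 1).all():
        return "study"
    if (per_ind["nunique"] == ops).all() and (per_ind["count"] == ops).all():
        return "replica"
    return "mixed"


def _provenance(dataset: LandmarkDataset, seed: int, settings: dict) -> dict:
    return {
        "input_sha256": dataset_hash(dataset),
        "n_records": len(dataset),
        "seed": seed,
        "software_version": _version(),
        "settings": settings,
    }


def _anova_block(table: anova.AnovaTable, icc: anova.IccResult | None = None) -> dict:
    out = table.to_dict()
    if icc is not None:
        out["icc"] = icc.to_dict()
    return out


def run_replica_analysis(
    dataset: LandmarkDataset, seed: int = 0, n_permutations: int = 0
) -> dict:
    """Stages I and II on subsets all/bone/nose of a full-replica dataset."""
    design = detect_design(dataset)
    if design != "replica":
        raise ValueError(
            f"dataset is a {design!r} design; use run_study_analysis for "
            "partition designs"
        )
    t0 = time.perf_counter()
    settings = {
        "icc_variant": "symmetric",
        "percentile_method": abserr.PERCENTILE_METHOD,
        "trim_fraction": 0.05,
        "n_permutations": n_permutations,
    }
    report: dict = {
        "kind": "replica",
        "subsets": {},
        "provenance": _provenance(dataset, seed, settings),
    }
    operators = tuple(dict.fromkeys(dataset.meta()["operator_id"]))
    for subset in SUBSETS:
        ds = dataset.select_subset(subset)
        meta = ds.meta()
        log.info("replica subset=%s n=%d p=%d", subset, len(ds), ds.panel.size)

        err_table = abserr.compute_odev_avedev(ds)
        profile = abserr.error_profile(err_table)
        block: dict = {
            "absolute_error": {
                "profile": profile.reset_index().to_dict(orient="records"),
                "percentile_method": abserr.PERCENTILE_METHOD,
            }
        }
        if subset == "all":
            block["absolute_error"]["tissue_contrast"] = abserr.tissue_error_contrast(
                err_table, ds.panel
            )

        cs = np.array([centroid_size(r.coords) for r in ds.records])
        fit = gpa_align(ds)
        ids = meta["individual_id"].to_numpy()
        ops = meta["operator_id"].to_numpy()

        t_size, icc_size = anova.repeatability_anova(
            cs, ids, trait="size", subset=subset,
            n_permutations=n_permutations, seed=seed,
        )
        t_shape, icc_shape = anova.repeatability_anova(
            fit, ids, trait="shape", subset=subset,
            n_permutations=n_permutations, seed=seed,
        )
        block["repeatability"] = {
            "size": _anova_block(t_size, icc_size),
            "shape": _anova_block(t_shape, icc_shape),
        }
        block["operator_grouping"] = {
            "size": _anova_block(
                anova.grouping_anova(cs, ops, trait="size", subset=subset)
            ),
            "shape": _anova_block(
                anova.grouping_anova(fit, ops, trait="shape", subset=subset)
            ),
        }

        cs_by_op = {
            op: pd.Series(cs[ops == op], index=ids[ops == op]) for op in operators
        }
        size_corr, size_mean = concordance.pairwise_size_correlation(cs_by_op)
        dm = shape_distance_matrix(fit)
        per_op_dm = {}
        for op in operators:
            sel = np.flatnonzero(ops == op)
            per_op_dm[op] = type(dm)(
                labels=tuple(ids[sel]), values=dm.values[np.ix_(sel, sel)]
            )
        shape_corrs = {}
        for a_i, a in enumerate(operators):
            for b in operators[a_i + 1:]:
                shape_corrs[f"{a}-{b}"] = concordance.distance_matrix_correlation(
                    per_op_dm[a], per_op_dm[b]
                )
        tree = concordance.upgma_tree(dm)
        individual_of = dict(zip(fit.labels, ids))
        counts = concordance.replica_cluster_counts(tree, individual_of)
        d2m = distance_to_mean(fit)
        rng_stat = concordance.relative_range(d2m, trim_fraction=0.05)
        block["concordance"] = {
            "size_correlations": size_corr.to_dict(),
            "size_correlation_mean": size_mean,
            "shape_matrix_correlations": shape_corrs,
            "shape_matrix_correlation_mean": concordance.mean_shape_correlation(
                shape_corrs.values()
            ),
            "upgma_newick": str(tree),
            "cluster_counts": counts.to_dict(),
            "relative_range": rng_stat.to_dict(),
        }

        pca = ordination.shape_pca(fit)
        block["pca"] = {
            "percent_variance_top5": [float(v) for v in pca.percent_variance[:5]],
            "n_components": pca.m,
            "total_variance": pca.total_variance,
        }
        report["subsets"][subset] = block
    report["elapsed_s"] = round(time.perf_counter() - t0, 3)
    return report


def run_study_analysis(
    dataset: LandmarkDataset,
    seed: int = 0,
    balanced_n: int | None = None,
) -> dict:
    """Stage III on a partition-design dataset with sex labels."""
    design = detect_design(dataset)
    if design != "study":
        raise ValueError(
            f"dataset is a {design!r} design; use run_replica_analysis for "
            "full-replica designs"
        )
    meta_all = dataset.meta()
    if set(meta_all["sex"]) <= {"unknown"}:
        raise ValueError("study analysis requires sex labels")
    t0 = time.perf_counter()
    settings = {"balanced_n": balanced_n, "trim_fraction": 0.05}
    report: dict = {
        "kind": "study",
        "subsets": {},
        "provenance": _provenance(dataset, seed, settings),
    }
    for subset in SUBSETS:
        ds = dataset.select_subset(subset)
        meta = ds.meta()
        log.info("study subset=%s n=%d p=%d", subset, len(ds), ds.panel.size)
        cs = np.array([centroid_size(r.coords) for r in ds.records])
        fit = gpa_align(ds)
        sex = meta["sex"].to_numpy()
        ops = meta["operator_id"].to_numpy()
        block = {
            "hierarchical": {
                "size": _anova_block(
                    anova.hierarchical_anova(cs, sex, ops, trait="size", subset=subset)
                ),
                "shape": _anova_block(
                    anova.hierarchical_anova(fit, sex, ops, trait="shape", subset=subset)
                ),
            }
        }
        d2m = distance_to_mean(fit)
        block["relative_range"] = concordance.relative_range(
            d2m, trim_fraction=0.05
        ).to_dict()
        pca = ordination.shape_pca(fit)
        records, centroids = ordination.group_scatter_export(pca, sex, ops)
        block["pca"] = {
            "percent_variance_top5": [float(v) for v in pca.percent_variance[:5]],
            "n_components": pca.m,
            "total_variance": pca.total_variance,
            "group_centroids": centroids.to_dict(orient="records"),
        }
        if balanced_n is not None:
            bal_table, bal_ids = anova.balanced_subsample_r2(
                ds, balanced_n, seed=seed, trait="shape"
            )
            bal_size, _ids2 = anova.balanced_subsample_r2(
                ds, balanced_n, seed=seed, trait="size"
            )
            block["balanced_subsample"] = {
                "n_per_cell": balanced_n,
                "n_total": len(bal_ids),
                "shape": _anova_block(bal_table),
                "size": _anova_block(bal_size),
                "sampled_ids": list(bal_ids),
            }
        report["subsets"][subset] = block
    report["elapsed_s"] = round(time.perf_counter() - t0, 3)
    return report


def report_to_json(report: dict) -> str:
    """Deterministic JSON serialization (sorted keys, exact float reprs)."""
    stripped = {k: v for k, v in report.items() if k != "elapsed_s"}
    return json.dumps(stripped, sort_keys=True, indent=1, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def render_text(report: dict) -> str:
    """Human-readable summary with table-style rounding (whole-percent R2,
    2-decimal ICC and correlations); every number also appears unrounded in
    the JSON report."""
    lines = [f"morphoerror {report['kind']} report", "=" * 34]
    for subset, block in report["subsets"].items():
        lines.append(f"\n[{subset}]")
        if "repeatability" in block:
            for trait in ("size", "shape"):
                t = block["repeatability"][trait]
                r2s = {r["effect"]: r["R2"] for r in t["rows"]}
                icc = t["icc"]["icc"]
                lines.append(
                    f"  repeatability {trait}: "
                    + " ".join(f"{e} R2={v:.0f}%" for e, v in r2s.items())
                    + f" ICC={icc:.2f}"
                )
            for trait in ("size", "shape"):
                t = block["operator_grouping"][trait]
                r2s = {r["effect"]: r["R2"] for r in t["rows"]}
                lines.append(
                    f"  operator grouping {trait}: "
                    + " ".join(f"{e} R2={v:.0f}%" for e, v in r2s.items())
                )
            cc = block["concordance"]
            lines.append(
                f"  size r(mean)={cc['size_correlation_mean']:.2f} "
                f"shape matrix r(mean)={cc['shape_matrix_correlation_mean']:.2f}"
            )
            k = cc["cluster_counts"]
            lines.append(
                f"  UPGMA: {k['n_triplets']}/{k['n_individuals']} triplets, "
                f"{k['n_pairs_or_better']}/{k['n_individuals']} pairs-or-better"
            )
        if "hierarchical" in block:
            for trait in ("size", "shape"):
                t = block["hierarchical"][trait]
                r2s = {r["effect"]: r["R2"] for r in t["rows"]}
                lines.append(
                    f"  hierarchical {trait}: "
                    + " ".join(f"{e} R2={v:.0f}%" for e, v in r2s.items())
                )
    return "\n".join(lines) + "\n"
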