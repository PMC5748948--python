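"""Manifest-driven batch processing and group-level analysis.

A manifest is a table with one row per image and the columns ``embryo_id``,
``timepoint`` (``0hpi`` or ``72hpi``) and ``image_path``; any further columns
are treated as group labels and carried through to the results.  Every embryo
must appear exactly twice, once per timepoint — this is validated before a
single image is read.

Embryos whose baseline measurement is undefined (blank or sub-threshold
0 hpi signal) are reported in a discard table, never silently dropped: the
decision to exclude an embryo is a biological one, so the tool surfaces it.
"""

from __future__ import annotations

import logging

import pandas as pd

from .errors import GfpQuantError, ManifestError, UndefinedBaselineError
from .image import EmbryoImageRecord, load_gfp_image
from .quantify import DEFAULT_T_MAX, DEFAULT_TOLERANCE, proliferation_index
from .stats import compare_groups, iqr_filter

__all__ = ["validate_manifest", "run_batch", "run_group_analysis"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("embryo_id", "timepoint", "image_path")


def validate_manifest(manifest: pd.DataFrame) -> list[str]:
    """Check structure and pairing; return the group-label column names."""
    missing = [c for c in REQUIRED_COLUMNS if c not in manifest.columns]
    if missing:
        raise ManifestError(f"manifest is missing required columns: {missing}")
    bad_tp = manifest.loc[~manifest["timepoint"].isin(["0hpi", "72hpi"]), "timepoint"]
    if len(bad_tp):
        raise ManifestError(f"unknown timepoint values: {sorted(set(bad_tp))}")
    for embryo_id, sub in manifest.groupby("embryo_id", sort=False):
        tps = sorted(sub["timepoint"])
        if tps != ["0hpi", "72hpi"]:
            raise ManifestError(
                f"embryo {embryo_id!r} must have exactly one 0hpi and one 72hpi "
                f"row, found timepoints {tps}"
            )
    return [c for c in manifest.columns if c not in REQUIRED_COLUMNS]


def run_batch(
    manifest: pd.DataFrame,
    tolerance: float = DEFAULT_TOLERANCE,
    t_max: int = DEFAULT_T_MAX,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process every embryo in the manifest.

    Returns ``(results, discards)``: one row per successfully measured embryo
    in ``results`` and one row (embryo_id, reason) per failed embryo in
    ``discards``.  Results are sorted by embryo_id, so the output is
    independent of manifest row order.
    """
    group_cols = validate_manifest(manifest)
    results: list[dict] = []
    discards: list[dict] = []
    for embryo_id, sub in sorted(manifest.groupby("embryo_id", sort=False),
                                 key=lambda kv: str(kv[0])):
        sub = sub.sort_values("timepoint")
        row0, row72 = sub.iloc[0], sub.iloc[1]
        labels = {c: row0[c] for c in group_cols}
        try:
            rec0 = EmbryoImageRecord(
                embryo_id=str(embryo_id), timepoint="0hpi",
                image=load_gfp_image(row0["image_path"]), group=labels,
            )
            rec72 = EmbryoImageRecord(
                embryo_id=str(embryo_id), timepoint="72hpi",
                image=load_gfp_image(row72["image_path"]), group=labels,
            )
            res = proliferation_index(rec0, rec72, tolerance=tolerance, t_max=t_max)
        except (UndefinedBaselineError, GfpQuantError, IOError) as exc:
            logger.warning("discarding embryo %s: %s", embryo_id, exc)
            discards.append({"embryo_id": str(embryo_id), "reason": str(exc), **labels})
            continue
        logger.info(
            "embryo %s: thresholds %s/%s shared %d PI %.4f",
            embryo_id, res.flags.get("threshold_0"), res.flags.get("threshold_72"),
            res.shared_threshold, res.PI,
        )
        results.append(
            {
                "embryo_id": str(embryo_id),
                **labels,
                "shared_threshold": res.shared_threshold,
                "nGFP_0": res.m0.nGFP,
                "GMV_0": res.m0.GMV,
                "nGFP_72": res.m72.nGFP,
                "GMV_72": res.m72.GMV,
                "PI": res.PI,
                "classification": res.classification,
                "flat_curve_0": res.flags["flat_curve_0"],
                "flat_curve_72": res.flags["flat_curve_72"],
                "saturated_0": res.flags["saturated_0"],
                "saturated_72": res.flags["saturated_72"],
            }
        )
    res_cols = ["embryo_id", *group_cols, "shared_threshold", "nGFP_0", "GMV_0",
                "nGFP_72", "GMV_72", "PI", "classification",
                "flat_curve_0", "flat_curve_72", "saturated_0", "saturated_72"]
    return (
        pd.DataFrame(results, columns=res_cols),
        pd.DataFrame(discards, columns=["embryo_id", "reason", *group_cols]),
    )


def run_group_analysis(
    results: pd.DataFrame,
    grouping: str | list[str],
    alpha: float = 0.05,
    iqr_k: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group PI summaries (after IQR outlier removal) and pairwise tests.

    Returns ``(group_summary, pairwise)``.  Requires at least two groups.
    """
    cols = [grouping] if isinstance(grouping, str) else list(grouping)
    groups = {
        key if isinstance(key, str) else "/".join(map(str, key)): sub["PI"].tolist()
        for key, sub in results.groupby(cols, sort=True)
    }
    if len(groups) < 2:
        raise ValueError(f"group analysis needs >= 2 groups, found {len(groups)}")

    summaries = []
    filtered: dict[str, list[float]] = {}
    for name, values in groups.items():
        if len(values) >= 4:
            kept, outliers = iqr_filter(values, k=iqr_k)
        else:  # too few for fences; keep everything
            kept, outliers = list(values), []
        filtered[name] = kept
        summaries.append(
            {
                "group": name,
                "n_total": len(values),
                "n_kept": len(kept),
                "n_outliers": len(outliers),
                "mean_PI": float(pd.Series(kept).mean()) if kept else float("nan"),
            }
        )

    pairwise = []
    names = sorted(filtered)
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            cmp = compare_groups(filtered[na], filtered[nb], alpha=alpha)
            pairwise.append(
                {
                    "group_a": na,
                    "group_b": nb,
                    "test_used": cmp.test_used,
                    "homoscedastic": cmp.homoscedastic,
                    "statistic": cmp.statistic,
                    "p_value": cmp.p_value,
                    "alpha": cmp.alpha,
                    "significant": cmp.significant,
                }
            )
    return pd.DataFrame(summaries), pd.DataFrame(pairwise)
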