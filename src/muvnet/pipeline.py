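"""Batch orchestration, provenance, and group-comparison statistics.

`run_device` composes the segmentation and metric stages into one
deterministic per-device record; `run_batch` applies it over a
configured set of images, recording failures without aborting the
batch.  `compare_groups` provides the statistical plumbing used for
per-condition summaries: means with standard deviations, an unpaired
two-tailed t-test for two groups, one-way ANOVA for more than two
groups at a single time point, and two-way ANOVA with Bonferroni-
adjusted post hoc pairwise comparisons for time courses.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.draw import polygon2mask

from .segment import (
    BinaryMask,
    FilterParams,
    GrayImage,
    ValidationError,
    binarize,
    filter_components,
    label_components,
)
from .metrics import (
    NetworkMetrics,
    anastomosis_fraction,
    mean_diameter,
    vessel_density,
)
from .synthgen import DeviceGeometry, make_default_geometry

__all__ = [
    "RunConfig",
    "GroupSummary",
    "params_hash",
    "bonferroni",
    "run_device",
    "run_batch",
    "compare_groups",
]

METRIC_COLUMNS = ("density", "mean_diameter_um", "anastomosis_fraction")


@dataclass
class RunConfig:
    """Configuration for a batch run over device images.

    ``inputs`` is a list of records with ``path``, ``device_id`` and
    ``condition`` keys; analysis parameters apply to every device.
    ``roi`` is an optional (x, y) pixel-polygon restricting the density
    computation; ``exclusion_polygons`` feed the shape filter.
    """

    inputs: list[dict] = field(default_factory=list)
    pixel_size: float = 2.0
    bit_depth: int = 16
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_area_px: int = 200
    min_eccentricity: float = 0.8
    filter_rule: str = "or"
    connectivity: int = 8
    exclusion_polygons: list = field(default_factory=list)
    pore_window_radius: float = 75.0
    coverage_min: float = 0.1
    roi: list | None = None
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for rec in cfg.inputs:
            if not Path(rec["path"]).exists():
                raise ValidationError(f"input path does not exist: {rec['path']}")
            if not str(rec.get("condition", "")):
                raise ValidationError("every input needs a nonempty condition label")
        return cfg

    def analysis_params(self) -> dict:
        d = asdict(self)
        d.pop("inputs")
        d.pop("out_dir")
        return d


def params_hash(params: dict) -> str:
    """Short stable hash of an analysis-parameter dict, for provenance."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p), exactly."""
    return min(1.0, m * p)


def _segment_image(config: RunConfig, image: GrayImage) -> BinaryMask:
    mask = binarize(image, method=config.threshold_method,
                    fixed_threshold=config.fixed_threshold)
    regions = label_components(mask, connectivity=config.connectivity)
    params = FilterParams(
        min_area_px=config.min_area_px,
        min_eccentricity=config.min_eccentricity,
        rule=config.filter_rule,
        exclusion_polygons=config.exclusion_polygons,
    )
    return filter_components(mask, regions, params,
                             connectivity=config.connectivity)


def run_device(
    config: RunConfig,
    image: GrayImage,
    geometry: DeviceGeometry | None = None,
) -> NetworkMetrics:
    """Run the full single-device pipeline on one composite image.

    Binarize, label, shape-filter, then measure density (within the
    configured ROI or the full frame), mean diameter, and anastomosis
    fraction against the device geometry (the default 54-pore layout
    unless one is supplied).  Deterministic for fixed inputs and
    parameters.  An all-background image yields density 0, anastomosis
    0 and the 0 μm diameter sentinel.
    """
    if geometry is None:
        geometry = make_default_geometry(config.pore_window_radius)
    filtered = _segment_image(config, image)
    notes: list[str] = []
    if not filtered.pixels.any():
        notes.append("no vessel foreground after filtering")
        diam = 0.0
    else:
        diam = mean_diameter(filtered)
    return NetworkMetrics(
        density=vessel_density(filtered, roi=config.roi),
        mean_diameter_um=diam,
        anastomosis_fraction=anastomosis_fraction(
            filtered, geometry, coverage_min=config.coverage_min
        ),
        roi_area_px=(
            filtered.pixels.size if config.roi is None
            else int(np.count_nonzero(polygon2mask(
                filtered.pixels.shape,
                np.asarray(config.roi, dtype=float)[:, ::-1],
            )))
        ),
        warnings=notes,
    )


def run_batch(config: RunConfig, geometry: DeviceGeometry | None = None) -> pd.DataFrame:
    """Apply `run_device` to every configured input image.

    Per-device failures (unreadable or mis-sized images) are recorded in
    the output table's ``error`` column and the batch continues.  When
    ``config.out_dir`` is set, a JSON record per device and an appended
    batch CSV (``metrics.csv``) are written, each row carrying the
    parameter hash for provenance.
    """
    import tifffile

    phash = params_hash(config.analysis_params())
    rows = []
    for rec in config.inputs:
        row = {
            "device_id": rec.get("device_id", Path(rec["path"]).stem),
            "condition": rec["condition"],
            "params_hash": phash,
        }
        try:
            pixels = tifffile.imread(rec["path"])
            image = GrayImage(pixels=pixels, pixel_size=config.pixel_size,
                              bit_depth=config.bit_depth)
            m = run_device(config, image, geometry=geometry)
            row.update(m.to_json_dict())
            row["error"] = ""
        except (OSError, ValidationError, ValueError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for row in rows:
            (out / f"{row['device_id']}.json").write_text(
                json.dumps(row, indent=2, sort_keys=True)
            )
        csv_path = out / "metrics.csv"
        table.to_csv(csv_path, mode="a", header=not csv_path.exists(), index=False)
    return table


@dataclass
class GroupSummary:
    """Per-condition descriptive statistics and hypothesis tests.

    ``summary`` holds n, mean and standard deviation per group and
    metric; ``tests`` one row per (metric[, comparison]) with the test
    name, statistic, raw p and Bonferroni-adjusted p (adjusted ≥ raw).
    """

    summary: pd.DataFrame
    tests: pd.DataFrame


def compare_groups(
    records: pd.DataFrame,
    group_col: str = "condition",
    metrics: Sequence[str] | None = None,
    time_col: str | None = None,
    equal_var: bool = True,
) -> GroupSummary:
    """Summarise metrics per group and test for group differences.

    Two groups: unpaired two-tailed Student's t-test (Welch via
    ``equal_var=False``).  More than two groups at a single time point:
    one-way ANOVA.  With ``time_col`` given (a time course): two-way
    ANOVA (group, time, interaction) plus post hoc pairwise group
    t-tests within each time point, Bonferroni-adjusted over all
    pairwise comparisons.  A single group yields the summary only.
    """
    if metrics is None:
        metrics = [c for c in METRIC_COLUMNS if c in records.columns]
    if not metrics:
        raise ValidationError("no metric columns found to compare")
    if group_col not in records.columns:
        raise ValidationError(f"missing grouping column {group_col!r}")
    groups = sorted(records[group_col].dropna().unique().tolist())
    if len(groups) == 0:
        raise ValidationError("no groups present")

    summary = (
        records.groupby(group_col)[list(metrics)]
        .agg(["count", "mean", "std"])
        .rename(columns={"count": "n", "std": "sd"}, level=1)
    )

    test_rows: list[dict] = []
    if len(groups) >= 2:
        if time_col is None:
            for metric in metrics:
                samples = [
                    records.loc[records[group_col] == g, metric].to_numpy()
                    for g in groups
                ]
                if len(groups) == 2:
                    t, p = stats.ttest_ind(samples[0], samples[1],
                                           equal_var=equal_var)
                    name = "t-test" if equal_var else "welch-t"
                    test_rows.append({
                        "metric": metric, "test": name,
                        "comparison": f"{groups[0]} vs {groups[1]}",
                        "statistic": float(t), "p": float(p),
                        "p_adjusted": bonferroni(float(p), 1),
                    })
                else:
                    f, p = stats.f_oneway(*samples)
                    test_rows.append({
                        "metric": metric, "test": "one-way ANOVA",
                        "comparison": " vs ".join(map(str, groups)),
                        "statistic": float(f), "p": float(p),
                        "p_adjusted": bonferroni(float(p), 1),
                    })
        else:
            import statsmodels.api as sm
            import statsmodels.formula.api as smf

            times = sorted(records[time_col].dropna().unique().tolist())
            pairs = list(combinations(groups, 2))
            m = len(pairs) * len(times)
            for metric in metrics:
                df = records[[group_col, time_col, metric]].rename(
                    columns={group_col: "grp", time_col: "tm", metric: "y"}
                )
                model = smf.ols("y ~ C(grp) * C(tm)", data=df).fit()
                aov = sm.stats.anova_lm(model, typ=2)
                for term, label in (("C(grp)", "group"), ("C(tm)", "time"),
                                    ("C(grp):C(tm)", "interaction")):
                    test_rows.append({
                        "metric": metric, "test": f"two-way ANOVA ({label})",
                        "comparison": "all",
                        "statistic": float(aov.loc[term, "F"]),
                        "p": float(aov.loc[term, "PR(>F)"]),
                        "p_adjusted": bonferroni(float(aov.loc[term, "PR(>F)"]), 1),
                    })
                for tm in times:
                    sub = df[df["tm"] == tm]
                    for a, b in pairs:
                        xa = sub.loc[sub["grp"] == a, "y"].to_numpy()
                        xb = sub.loc[sub["grp"] == b, "y"].to_numpy()
                        if len(xa) < 2 or len(xb) < 2:
                            continue
                        t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
                        test_rows.append({
                            "metric": metric, "test": "post hoc t (Bonferroni)",
                            "comparison": f"{a} vs {b} @ {time_col}={tm}",
                            "statistic": float(t), "p": float(p),
                            "p_adjusted": bonferroni(float(p), m),
                        })
    tests = pd.DataFrame(
        test_rows,
        columns=["metric", "test", "comparison", "statistic", "p", "p_adjusted"],
    )
    return GroupSummary(summary=summary, tests=tests)
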