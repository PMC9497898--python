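"""Repeatability (CV), reliability (RPD, ICC), feature exclusion, study driver.

The repeatability unit is the coefficient of variation over repeated scans,
CV = std/mean * 100 (sample standard deviation). Between-setup agreement uses
the relative percentage difference RPD = (m1 - m2)/m1 * 100 over the 14
canonical setup pairs, and the intraclass correlation

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

from a two-way ANOVA of n objects by k setups (absolute agreement, single
measurement), categorized as excellent (> 0.9), good (> 0.75), moderate
(> 0.5) or poor. Features whose aggregated CV exceeds 10% are flagged
unstable and excluded.

Undefined CVs (zero mean, which normalized intensities produce by
construction) are recorded as NaN, dropped from averages and counted in a QC
log, never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import phantom_forge, texturex, virtual_mr, voiprep

__all__ = [
    "cv",
    "rpd",
    "comparison_pairs",
    "ICCResult",
    "icc",
    "cv_table",
    "exclude_unstable",
    "summarize_cv",
    "synthetic_repeat_table",
    "StudyConfig",
    "run_study",
]

META_COLUMNS = ["object", "setup", "repetition"]


def cv(values) -> float:
    """Coefficient of variation in percent; NaN when the mean is zero."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 repetitions")
    m = v.mean()
    if m == 0:
        return float("nan")
    return float(v.std(ddof=1) / m * 100.0)


def rpd(mean1: float, mean2: float) -> float:
    """Signed relative percentage difference with setup-1 denominator."""
    if mean1 == 0:
        return float("nan")
    return float((mean1 - mean2) / mean1 * 100.0)


def comparison_pairs() -> list[tuple[str, int, int]]:
    """The 14 canonical setup comparisons as (label, row1, row2).

    Rows are 1-based indices into :func:`texphan.virtual_mr.enumerate_setups`;
    7 T1 pairs and their 7 T2 mirrors, spanning resolution, field-strength and
    coil contrasts at matched discretization (FBS rows).
    """
    t1 = [
        ("1.5T_T1_6ch_1mm-2mm", 1, 3),
        ("1.5T_T1_6ch-3T_T1_8ch_1mm", 1, 5),
        ("1.5T_T1_6ch-3T_T1_8ch_2mm", 3, 7),
        ("3T_T1_8ch_1mm-2mm", 5, 7),
        ("3T_T1_8ch-32ch_1mm", 5, 9),
        ("3T_T1_8ch-32ch_2mm", 7, 11),
        ("3T_T1_32ch_1mm-2mm", 9, 11),
    ]
    t2 = [(lbl.replace("T1", "T2"), a + 12, b + 12) for lbl, a, b in t1]
    return t1 + t2


@dataclass
class ICCResult:
    icc: float
    MSR: float
    MSC: float
    MSE: float
    n: int
    k: int

    @property
    def category(self) -> str:
        if not np.isfinite(self.icc):
            return "undefined"
        if self.icc > 0.9:
            return "excellent"
        if self.icc > 0.75:
            return "good"
        if self.icc > 0.5:
            return "moderate"
        return "poor"


def icc(matrix) -> ICCResult:
    """Two-way ANOVA intraclass correlation (absolute agreement, single unit).

    ``matrix`` has one row per object and one column per setup, each cell the
    mean over that object's repetitions. Negative ICCs are legitimate output
    (high disagreement); a zero-variance matrix yields NaN.
    """
    x = np.asarray(matrix, dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs at least 2 objects and 2 setups")
    grand = x.mean()
    rowm = x.mean(axis=1)
    colm = x.mean(axis=0)
    msr = k * ((rowm - grand) ** 2).sum() / (n - 1)
    msc = n * ((colm - grand) ** 2).sum() / (k - 1)
    resid = x - rowm[:, None] - colm[None, :] + grand
    mse = (resid ** 2).sum() / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    val = float("nan") if denom == 0 else (msr - mse) / denom
    return ICCResult(icc=float(val), MSR=float(msr), MSC=float(msc),
                     MSE=float(mse), n=n, k=k)


# --------------------------------------------------------------------------
# Tables
# --------------------------------------------------------------------------

def cv_table(repeat_df: pd.DataFrame) -> pd.DataFrame:
    """Per (object, setup, feature) CV over repetitions, long form."""
    features = [c for c in repeat_df.columns if c not in META_COLUMNS]
    rows = []
    for (obj, setup), grp in repeat_df.groupby(["object", "setup"], sort=False):
        for feat in features:
            rows.append({"object": obj, "setup": setup, "feature": feat,
                         "cv": cv(grp[feat].to_numpy())})
    return pd.DataFrame(rows)


def rpd_table(repeat_df: pd.DataFrame) -> pd.DataFrame:
    """Signed RPD per (object, comparison, feature) over the 14 pairs."""
    setups = [s.label for s in virtual_mr.enumerate_setups()]
    features = [c for c in repeat_df.columns if c not in META_COLUMNS]
    means = repeat_df.groupby(["object", "setup"], sort=False)[features].mean()
    rows = []
    for lbl, r1, r2 in comparison_pairs():
        s1, s2 = setups[r1 - 1], setups[r2 - 1]
        for obj in repeat_df["object"].unique():
            if (obj, s1) not in means.index or (obj, s2) not in means.index:
                continue
            for feat in features:
                rows.append({
                    "object": obj, "comparison": lbl, "feature": feat,
                    "rpd": rpd(means.loc[(obj, s1), feat],
                               means.loc[(obj, s2), feat]),
                })
    return pd.DataFrame(rows)


def icc_table(repeat_df: pd.DataFrame) -> pd.DataFrame:
    """ICC per (comparison, feature) across objects, Fig-8 style."""
    setups = [s.label for s in virtual_mr.enumerate_setups()]
    features = [c for c in repeat_df.columns if c not in META_COLUMNS]
    means = repeat_df.groupby(["object", "setup"], sort=False)[features].mean()
    objects = list(repeat_df["object"].unique())
    rows = []
    for lbl, r1, r2 in comparison_pairs():
        s1, s2 = setups[r1 - 1], setups[r2 - 1]
        have = [o for o in objects
                if (o, s1) in means.index and (o, s2) in means.index]
        if len(have) < 2:
            continue
        for feat in features:
            mat = np.array([[means.loc[(o, s1), feat],
                             means.loc[(o, s2), feat]] for o in have])
            res = icc(mat)
            rows.append({"comparison": lbl, "feature": feat, "icc": res.icc,
                         "category": res.category})
    return pd.DataFrame(rows)


def exclude_unstable(
    cv_df: pd.DataFrame, threshold: float = 10.0, aggregation: str = "mean"
) -> tuple[list[str], dict[str, float]]:
    """Split features into retained and excluded by aggregated CV.

    ``aggregation="mean"`` excludes a feature when its mean CV over all
    objects and setups exceeds ``threshold`` percent; ``"any"`` excludes when
    any single (object, setup) CV does. Undefined CVs are ignored.
    Returns (retained names, {excluded name: offending CV}).
    """
    agg = {"mean": "mean", "any": "max"}[aggregation]
    per_feature = cv_df.groupby("feature")["cv"].agg(agg)
    excluded = {f: float(v) for f, v in per_feature.items()
                if np.isfinite(v) and v > threshold}
    retained = [f for f in per_feature.index if f not in excluded]
    return retained, excluded


def _setup_properties(label: str) -> dict[str, str]:
    s = virtual_mr.parse_setup_label(label)
    return {
        "field": "1.5T" if s.field_T == 1.5 else "3T",
        "voxel": f"{int(s.voxel_mm)}mm",
        "weighting": s.weighting,
        "discretization": s.discretization,
    }


def summarize_cv(cv_df: pd.DataFrame, group_by: str = "field") -> pd.DataFrame:
    """Mean of defined CVs per object for each group of a setup property.

    ``group_by`` is one of ``field``, ``voxel``, ``weighting``,
    ``discretization``, ``family`` (feature family) or ``object``; the output
    mirrors the object-by-property-group layout of the study's summary tables.
    """
    df = cv_df.dropna(subset=["cv"]).copy()
    if group_by == "object":
        return df.groupby("object")["cv"].mean().to_frame("cv_average")
    if group_by == "family":
        df["group"] = df["feature"].map(texturex.FEATURE_FAMILY)
    else:
        props = {lbl: _setup_properties(lbl)[group_by]
                 for lbl in df["setup"].unique()}
        df["group"] = df["setup"].map(props)
    return df.pivot_table(index="object", columns="group", values="cv",
                          aggfunc="mean")


def qc_undefined_cv(cv_df: pd.DataFrame) -> pd.DataFrame:
    """The (object, setup, feature) cells whose CV is undefined (zero mean)."""
    return cv_df[~np.isfinite(cv_df["cv"])].reset_index(drop=True)


# --------------------------------------------------------------------------
# Synthetic repeat tables (planted-effect studies)
# --------------------------------------------------------------------------

def synthetic_repeat_table(
    objects=("Hilbert", "largeQR", "smallQR"),
    n_rep: int = 3,
    seed: int = 0,
    normalized: bool = True,
    planted_features: tuple[str, ...] = (
        "Jmax", "Energy", "ClusterShade", "HGRE", "SRHGE", "LRHGE",
        "LZE", "LZLGE", "LZHGE"),
    base_cv: float = 2.0,
    planted_cv: float = 15.0,
    coarse_factor: float = 1.8,
    unnormalized_factor: float = 1.5,
) -> pd.DataFrame:
    """Feature table with planted repeatability structure, for method checks.

    Each (object, feature) gets a stable baseline value; repetition scatter is
    multiplicative with relative spread ``base_cv`` percent, amplified by
    ``coarse_factor`` at 2 mm setups, by ``unnormalized_factor`` when
    ``normalized`` is off, and raised to ``planted_cv`` percent for the nine
    ``planted_features`` (the intrinsically unstable ones).
    """
    rng = np.random.default_rng(seed)
    setups = [s.label for s in virtual_mr.enumerate_setups()]
    features = texturex.ALL_FEATURE_NAMES
    base = {(o, f): rng.uniform(5.0, 50.0) for o in objects for f in features}
    rows = []
    for obj in objects:
        for lbl in setups:
            coarse = "2mm" in lbl
            for rep in range(1, n_rep + 1):
                row = {"object": obj, "setup": lbl, "repetition": rep}
                for f in features:
                    rel = planted_cv if f in planted_features else base_cv
                    if coarse:
                        rel *= coarse_factor
                    if not normalized:
                        rel *= unnormalized_factor
                    row[f] = base[(obj, f)] * (1 + rng.normal(0, rel / 100.0))
                rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Study orchestration
# --------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Everything a full simulated repeatability study needs.

    Defaults reproduce the full acquisition matrix with three repetitions.
    ``phantoms`` maps object name -> zero-argument phantom builder; ``vois``
    maps object name -> ("cubic", edge_mm) or ("grow", [seed voxels]).
    """

    phantoms: dict = dc_field(default_factory=dict)
    setups: list = dc_field(default_factory=virtual_mr.enumerate_setups)
    n_rep: int = 3
    master_seed: int = 0
    normalize: bool = True
    vois: dict = dc_field(default_factory=dict)
    contrast: virtual_mr.ContrastModel = dc_field(
        default_factory=virtual_mr.ContrastModel)
    pad_mm: float = 10.0
    exclusion_threshold: float = 10.0


def _default_voi(volume, spec):
    kind = spec[0]
    if kind == "cubic":
        return voiprep.centered_cubic_voi(volume, spec[1])
    if kind == "grow":
        if len(spec) > 1 and spec[1]:
            seeds = spec[1]
        else:
            seeds = [tuple(s // 2 for s in volume.intensities.shape)]
        return voiprep.grow_voi(volume, seeds)
    raise ValueError(f"unknown VOI spec {spec!r}")


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> dict:
    """Forge -> scan -> VOI -> extract -> CV/RPD/ICC/exclusion, deterministic.

    Scans once per imaging protocol (discretization does not change the scan)
    and reuses the repetitions for the FBS and FBN rows. Returns a bundle of
    DataFrames; when ``out_dir`` is given, also writes ``features.csv``,
    ``cv.csv``, ``rpd.csv``, ``icc.csv``, ``excluded_features.json`` and CV
    heatmaps.
    """
    rows = []
    for obj_idx, (name, builder) in enumerate(sorted(config.phantoms.items())):
        phantom = builder()
        protocols: dict[str, list] = {}
        for setup in config.setups:
            key = setup.protocol_label
            if key not in protocols:
                import zlib
                base_seed = (config.master_seed * 100003 + obj_idx * 1009
                             + zlib.crc32(key.encode()) % 100000) % (2 ** 31)
                protocols[key] = virtual_mr.repeat_scan(
                    phantom, setup, config.n_rep, base_seed, config.contrast,
                    pad_mm=config.pad_mm)
            for vol in protocols[key]:
                mask = _default_voi(vol, config.vois.get(name, ("cubic", 20.0)))
                feats = texturex.extract_all(
                    vol, mask, setup.discretization, config.normalize)
                rows.append({"object": name, "setup": setup.label,
                             "repetition": vol.repetition_index, **feats})
    features = pd.DataFrame(rows)
    cvs = cv_table(features)
    rpds = rpd_table(features)
    iccs = icc_table(features)
    retained, excluded = exclude_unstable(cvs, config.exclusion_threshold)
    bundle = {
        "features": features,
        "cv": cvs,
        "rpd": rpds,
        "icc": iccs,
        "retained": retained,
        "excluded": excluded,
        "qc_undefined_cv": qc_undefined_cv(cvs),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        features.to_csv(out / "features.csv", index=False)
        cvs.to_csv(out / "cv.csv", index=False)
        rpds.to_csv(out / "rpd.csv", index=False)
        iccs.to_csv(out / "icc.csv", index=False)
        import json
        (out / "excluded_features.json").write_text(
            json.dumps({"retained": retained, "excluded": excluded}, indent=2))
        plot_cv_heatmap(cvs, out / "cv_heatmap.png")
    return bundle


def plot_cv_heatmap(cv_df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Feature-by-setup CV heatmap per object; returns the plotted grid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = cv_df.pivot_table(index="feature", columns="setup", values="cv",
                             aggfunc="mean")
    fig, ax = plt.subplots(
        figsize=(max(6, 0.4 * grid.shape[1]), max(6, 0.22 * grid.shape[0])))
    im = ax.imshow(grid.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(grid.shape[0]), grid.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="CV (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return grid
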