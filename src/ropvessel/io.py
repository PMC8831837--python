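"""File formats and report rendering: images, annotations, results
tables, cohort reports.

Fundus images (PNG/TIFF, 8- or 16-bit, grayscale or RGB) are reduced to
the green channel (best vessel contrast in fundus photography), scaled
to [0, 1], and inverted once at ingest so that vessels are bright for
all internal Radon-transform feature detection. Annotations are JSON:
per image, an ROP stage label and for each of the four temporal vessels
a seed point near the optic-disc margin and a distal target point.
Results are flat CSV, one row per image.
"""

from __future__ import annotations

import hashlib
import json

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .angles import EyeMeasurement
from .errors import FormatError, InvalidInputError
from .radon import IntensityImage
from .stats import (
    ALPHA,
    GroupSummary,
    anova_from_summary,
    pearson,
    summarize_groups,
    tukey_from_summary,
)

__all__ = [
    "read_image",
    "to_internal",
    "load_annotation",
    "validate_annotation",
    "measurement_row",
    "write_results",
    "read_results",
    "cohort_report",
    "correlation_table",
    "config_hash",
]

STAGE_VOCAB = ("none", "1", "2", "3")
VARIABLES = ("taa", "tva", "taw", "tvw")


def to_internal(array: np.ndarray) -> IntensityImage:
    """Convert a raw grayscale/RGB array to the internal bright-vessel
    IntensityImage: green channel of RGB, scaled to [0, 1] by dtype
    range, then inverted."""
    arr = np.asarray(array)
    if arr.ndim == 3:
        arr = arr[:, :, 1]
    elif arr.ndim != 2:
        raise FormatError(f"unsupported image dimensionality {arr.ndim}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    return IntensityImage(1.0 - arr)


def read_image(path, return_raw: bool = False):
    """Read a PNG/TIFF fundus image into internal polarity.

    Returns the inverted (bright-vessel) :class:`IntensityImage`; with
    ``return_raw=True`` also returns the raw grayscale array in display
    polarity.
    """
    try:
        arr = iio.imread(path)
    except Exception as exc:  # unreadable / truncated / unsupported
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    img = to_internal(arr)
    if return_raw:
        return img, 1.0 - img.pixels
    return img


def validate_annotation(ann: dict, image_shape=None) -> dict:
    """Validate the annotation schema, returning the annotation."""
    if "vessels" not in ann or not isinstance(ann["vessels"], list):
        raise InvalidInputError("annotation must contain a 'vessels' list")
    stage = str(ann.get("stage", "none"))
    if stage not in STAGE_VOCAB:
        raise InvalidInputError(f"stage {stage!r} not in {STAGE_VOCAB}")
    seen = set()
    for e in ann["vessels"]:
        key = (e.get("vessel"), e.get("arm"))
        if key[0] not in ("artery", "vein") or key[1] not in ("superior", "inferior"):
            raise InvalidInputError(f"bad vessel/arm pair {key}")
        if key in seen:
            raise InvalidInputError(f"duplicate annotation entry {key}")
        seen.add(key)
        for field in ("seed", "target"):
            pt = e.get(field)
            if pt is None or len(pt) != 2:
                raise InvalidInputError(f"{key}: missing {field}")
            if image_shape is not None:
                h, w = image_shape
                if not (0 <= pt[0] <= w - 1 and 0 <= pt[1] <= h - 1):
                    raise InvalidInputError(f"{key}: {field} {pt} out of bounds")
    return ann


def load_annotation(path, image_shape=None) -> dict:
    try:
        with open(path) as fh:
            ann = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read annotation {path}: {exc}") from exc
    return validate_annotation(ann, image_shape)


def measurement_row(image_id: str, stage: str, m: EyeMeasurement) -> dict:
    """Flatten one EyeMeasurement into a results-table row."""
    return {
        "image": image_id,
        "stage": stage,
        "taa": m.taa,
        "tva": m.tva,
        "taw": m.taw,
        "tvw": m.tvw,
        "taw_inferior_only": m.taw_inferior_only,
        "tvw_inferior_only": m.tvw_inferior_only,
        "skipped_arms": ";".join("/".join(map(str, s)) for s in m.skipped_arms),
        "error": "",
    }


def write_results(rows, path) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def read_results(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, keep_default_na=True)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read results {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# cohort report rendering


def _tukey_letters(tukey) -> dict:
    """Assign one letter per significant pair, shared by its two groups
    (the published tables' superscript convention)."""
    letters = {}
    alphabet = iter("bcdefghij")
    out: dict[str, str] = {}
    for p in tukey.pairs:
        if p.significant:
            letter = next(alphabet)
            out[p.group_a] = out.get(p.group_a, "") + letter
            out[p.group_b] = out.get(p.group_b, "") + letter
    return out


def _format_p(p: float) -> str:
    return "<0.0001" if p < 1e-4 else f"{p:.4f}"


def cohort_report(summaries_by_var: dict[str, list[GroupSummary]]) -> str:
    """Markdown report: per-variable group summary table with ANOVA p
    and Tukey significance letters."""
    lines = ["# Temporal vessel measurements by ROP stage", ""]
    for var, summaries in summaries_by_var.items():
        anova = anova_from_summary(summaries)
        letters = _tukey_letters(tukey_from_summary(summaries))
        unit = "degrees" if var in ("taa", "tva") else "pixels"
        lines.append(f"## {var.upper()} ({unit})")
        lines.append("")
        lines.append("| Stage | n | Median | Min, Max | Mean ± SD | Tukey |")
        lines.append("|---|---|---|---|---|---|")
        for s in summaries:
            med = f"{s.median:.2f}" if s.median is not None else ""
            mm = (f"{s.min:.2f}, {s.max:.2f}"
                  if s.min is not None and s.max is not None else "")
            lines.append(
                f"| {s.label} | {s.n} | {med} | {mm} "
                f"| {s.mean:.2f} ± {s.sd:.2f} | {letters.get(s.label, '')} |"
            )
        lines.append("")
        lines.append(
            f"One-way ANOVA: F({anova.df_between}, {anova.df_within}) = "
            f"{anova.F:.2f}, p {_format_p(anova.p)}. Groups sharing a Tukey "
            f"letter differ at alpha = {ALPHA}."
        )
        lines.append("")
    return "\n".join(lines)


def summaries_from_results(df: pd.DataFrame) -> dict[str, list[GroupSummary]]:
    """Group a results table by stage and summarize each variable."""
    from .errors import InsufficientGroupsError

    out = {}
    stages = [s for s in df["stage"].astype(str).unique()]
    for var in VARIABLES:
        if var not in df.columns:
            continue
        groups, labels = [], []
        for stage in stages:
            vals = df.loc[df["stage"].astype(str) == stage, var].dropna().to_numpy()
            if len(vals) >= 2:
                groups.append(vals)
                labels.append(stage)
        if len(groups) < 2:
            raise InsufficientGroupsError(
                f"variable {var!r}: fewer than 2 stage groups with n >= 2"
            )
        out[var] = summarize_groups(groups, labels)
    return out


def correlation_table(df: pd.DataFrame, variables=VARIABLES) -> pd.DataFrame:
    """Pairwise Pearson r / n / p over all images (stage-pooled)."""
    rows = []
    present = [v for v in variables if v in df.columns]
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            sub = df[[a, b]].dropna()
            if len(sub) < 3:
                continue
            res = pearson(sub[a].to_numpy(), sub[b].to_numpy())
            rows.append({"x": a, "y": b, "r": res.r, "n": res.n,
                         "t": res.t, "p": res.p})
    return pd.DataFrame(rows)


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping, for run logging."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
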