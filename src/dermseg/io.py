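"""Image, mask, fixture and metrics-table I/O.

Masks travel as 8-bit PNGs with values 0/255 and are binarized at
intensity > 127 on read.  Metric tables are CSV with one row per image;
experiment reports mirror the usual paired-test layout (per-condition
mean, standard error, standard deviation, 95% CI, then t, df and the
two-tailed significance of the pair).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .evaluation import PairedTestResult, SegmentationMetrics
from .synthetic import FixtureSpec

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_fixture",
    "read_fixture_spec",
    "metrics_to_row",
    "write_metrics_csv",
    "read_metrics_csv",
    "experiment_report_frame",
]

METRIC_COLUMNS = ["accuracy", "sensitivity", "specificity", "dice"]


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG/BMP image as an M x N x 3 uint8 array.

    Grayscale inputs are replicated to three channels; an alpha channel
    is dropped.
    """
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def write_image(path, img: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(img, dtype=np.uint8))


def read_mask(path) -> np.ndarray:
    """Read an 8-bit mask PNG, binarizing at intensity > 127."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_fixture(outdir, name: str, img, mask, spec: FixtureSpec) -> None:
    """Write an image/mask PNG pair plus a JSON sidecar of the spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_image(outdir / f"{name}.png", img)
    write_mask(outdir / f"{name}_mask.png", mask)
    (outdir / f"{name}.json").write_text(
        json.dumps(spec.to_dict(), indent=2, sort_keys=True) + "\n"
    )


def read_fixture_spec(path) -> FixtureSpec:
    raw = json.loads(Path(path).read_text())
    for key in ("center", "axes", "skin_rgb", "lesion_rgb", "artifacts"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return FixtureSpec(**raw)


def metrics_to_row(image_id: str, m: SegmentationMetrics) -> dict:
    return {
        "image": image_id,
        "accuracy": m.accuracy,
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "dice": m.dice,
        "tp": m.tp,
        "fp": m.fp,
        "fn": m.fn,
        "tn": m.tn,
    }


def write_metrics_csv(path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metrics_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "image" not in df.columns:
        raise ValueError(f"{path}: not a metrics table (no 'image' column)")
    return df.set_index("image")


def experiment_report_frame(
    results: dict[str, PairedTestResult], label_a: str, label_b: str
) -> pd.DataFrame:
    """Tabulate paired-test results, two rows (conditions) per metric."""
    rows = []
    for k, (metric, res) in enumerate(results.items(), start=1):
        for cond, mean, se, sd, ci in (
            (label_a, res.mean_a, res.se_a, res.sd_a, res.ci_a),
            (label_b, res.mean_b, res.se_b, res.sd_b, res.ci_b),
        ):
            rows.append(
                {
                    "metric": metric,
                    "pair": k,
                    "condition": cond,
                    "mean": mean,
                    "std_err": se,
                    "std_dev": sd,
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                    "t_value": res.t,
                    "df": res.df,
                    "sig_2tailed": res.p,
                    "significant": res.significant,
                }
            )
    return pd.DataFrame(rows)
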