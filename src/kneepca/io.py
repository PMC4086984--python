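"""Plain-text exchange formats: cycle CSVs, JSON manifests, reports.

Cycle files are comma-separated UTF-8 with a mandatory header
``cycle_id,pct,flexion_deg,abduction_deg,rotation_deg`` and '.' decimal
separator; every cycle must contribute exactly 101 rows with ``pct``
running 0..100.  A JSON manifest ties the per-subject files together
with the Cardan convention, the seed/config provenance and optional
posture / ground-truth values.  Angles are serialized at full double
precision so write-then-read round-trips exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .correction import CorrectionResult, SubjectSide
from .evaluation import EvaluationMetrics, GroupSummary, group_summary
from .exceptions import CycleFormatError
from .processing import AngleCycle, N_POINTS

__all__ = [
    "SubjectEntry",
    "Manifest",
    "read_cycles",
    "write_cycles",
    "read_manifest",
    "write_manifest",
    "write_dataset",
    "load_dataset",
    "write_report",
]

CSV_COLUMNS = ["cycle_id", "pct", "flexion_deg", "abduction_deg", "rotation_deg"]


class SubjectEntry(BaseModel):
    """One subject/side record in a dataset manifest."""

    subject: str
    side: str
    cycles_file: str
    posture: list[float] | None = None
    truth_deformity: float | None = None


class Manifest(BaseModel):
    """Dataset-level metadata and file index."""

    dataset_id: str
    convention: str = "YXZ"
    seed: int | None = None
    config: dict | None = None
    subjects: list[SubjectEntry] = Field(default_factory=list)


def read_cycles(path: str | Path) -> list[AngleCycle]:
    """Read and validate all cycles of one CSV file.

    Raises :class:`CycleFormatError` naming the file and offending
    cycle for wrong row counts, non-numeric fields, a bad header or
    duplicate ``(cycle_id, pct)`` pairs.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise CycleFormatError(f"{path}: unreadable CSV ({exc})") from exc
    if list(df.columns) != CSV_COLUMNS:
        raise CycleFormatError(
            f"{path}: header must be {','.join(CSV_COLUMNS)}"
        )
    for col in CSV_COLUMNS[1:]:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise CycleFormatError(
                f"{path}: non-numeric value in column {col!r} at data row {bad}"
            )
    if df.duplicated(subset=["cycle_id", "pct"]).any():
        dup = df[df.duplicated(subset=["cycle_id", "pct"])].iloc[0]
        raise CycleFormatError(
            f"{path}: duplicate (cycle_id={dup['cycle_id']}, pct={dup['pct']})"
        )
    side = "right" if "right" in path.stem else ("left" if "left" in path.stem else "right")
    cycles = []
    for cid, group in df.groupby("cycle_id", sort=True):
        if len(group) != N_POINTS:
            raise CycleFormatError(
                f"{path}: cycle {cid} has {len(group)} rows, expected {N_POINTS}"
            )
        group = group.sort_values("pct")
        if not np.array_equal(group["pct"].to_numpy(), np.arange(N_POINTS)):
            raise CycleFormatError(
                f"{path}: cycle {cid} pct values must run 0..100"
            )
        samples = group[CSV_COLUMNS[2:]].to_numpy(dtype=float)
        cycles.append(AngleCycle(samples, side=side, cycle_id=int(cid)))
    return cycles


def write_cycles(cycles: Sequence[AngleCycle], path: str | Path) -> Path:
    """Write cycles to the CSV dialect at full double precision."""
    path = Path(path)
    frames = []
    for c in cycles:
        frames.append(
            pd.DataFrame(
                {
                    "cycle_id": c.cycle_id,
                    "pct": np.arange(N_POINTS),
                    "flexion_deg": c.samples[:, 0],
                    "abduction_deg": c.samples[:, 1],
                    "rotation_deg": c.samples[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=lambda v: repr(float(v))
    )
    return path


def read_manifest(path: str | Path) -> Manifest:
    """Load and validate a manifest; referenced files must exist."""
    path = Path(path)
    manifest = Manifest.model_validate_json(path.read_text())
    for entry in manifest.subjects:
        f = path.parent / entry.cycles_file
        if not f.exists():
            raise FileNotFoundError(f"manifest references missing file {f}")
    return manifest


def write_manifest(manifest: Manifest, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(manifest.model_dump_json(indent=2))
    return path


def config_hash(config: dict | None) -> str:
    """Stable hash of a configuration dict for provenance stamps."""
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_dataset(
    cohort: Sequence[tuple[SubjectSide, object]],
    outdir: str | Path,
    dataset_id: str = "synthetic",
    config: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Write a generated cohort as cycle CSVs + manifest + truth sidecar.

    Ground truth goes to ``ground_truth.json`` next to the manifest,
    never merged into the observed files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    truth_sidecar = {}
    for subject, truth in cohort:
        fname = f"{subject.subject}_{subject.side}.csv"
        write_cycles(subject.cycles, outdir / fname)
        entries.append(
            SubjectEntry(
                subject=subject.subject,
                side=subject.side,
                cycles_file=fname,
                posture=None if subject.posture is None else list(subject.posture),
                truth_deformity=getattr(truth, "deformity", None),
            )
        )
        if truth is not None:
            truth_sidecar[f"{subject.subject}_{subject.side}"] = {
                "misalignment_deg": getattr(truth, "misalignment_deg", None),
                "misalignment": np.asarray(truth.misalignment).tolist(),
                "deformity": truth.deformity,
                "posture_true": np.asarray(truth.posture_true).tolist(),
            }
    manifest = Manifest(
        dataset_id=dataset_id, seed=seed, config=config, subjects=entries
    )
    write_manifest(manifest, outdir / "manifest.json")
    if truth_sidecar:
        (outdir / "ground_truth.json").write_text(
            json.dumps(truth_sidecar, indent=2)
        )
    return outdir / "manifest.json"


def load_dataset(manifest_path: str | Path) -> list[tuple[SubjectSide, float | None]]:
    """Read every subject/side of a dataset back into memory."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    out = []
    for entry in manifest.subjects:
        cycles = read_cycles(manifest_path.parent / entry.cycles_file)
        for c in cycles:
            c.side = entry.side
        subject = SubjectSide(
            subject=entry.subject,
            side=entry.side,
            cycles=cycles,
            posture=None if entry.posture is None else np.asarray(entry.posture),
        )
        out.append((subject, entry.truth_deformity))
    return out


def write_report(
    results: dict[str, CorrectionResult],
    metrics: Sequence[EvaluationMetrics],
    outdir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Emit the group-variability table, the posture table and a JSON
    dump of every fitted transform.

    ``table1.csv``: per-side mean/SD of profile SDs (degrees) and
    cross-talk r-squared, before and after correction.  ``table2.csv``:
    per-subject posture angles against ground truth.  ``report.json``:
    transfer matrices, eigenvalues, variance fractions, permutations,
    signs, seed and config hash at full double precision.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics = list(metrics)

    rows = []
    sides = sorted({m.side for m in metrics})
    for side in sides:
        g = group_summary(metrics, side=side)
        for label, before, after in (
            ("profile_sd_flexion_deg", "delta2_flex_before", "delta2_flex_after"),
            ("profile_sd_abduction_deg", "delta2_abd_before", "delta2_abd_after"),
            ("crosstalk_r2", "r2_before", "r2_after"),
        ):
            values_b = [getattr(m, before) for m in metrics if m.side == side]
            values_a = [getattr(m, after) for m in metrics if m.side == side]
            if label.startswith("profile_sd"):
                values_b = [np.sqrt(v) for v in values_b]
                values_a = [np.sqrt(v) for v in values_a]
            rows.append(
                {
                    "metric": label,
                    "side": side,
                    "mean_before": float(np.mean(values_b)),
                    "sd_before": float(np.std(values_b, ddof=1)) if g.n > 1 else 0.0,
                    "mean_after": float(np.mean(values_a)),
                    "sd_after": float(np.std(values_a, ddof=1)) if g.n > 1 else 0.0,
                    "n": g.n,
                }
            )
    table1 = outdir / "table1.csv"
    pd.DataFrame(
        rows,
        columns=[
            "metric", "side", "mean_before", "sd_before",
            "mean_after", "sd_after", "n",
        ],
    ).to_csv(table1, index=False)

    posture_rows = [
        {
            "subject": m.subject,
            "side": m.side,
            "posture_before_deg": m.posture_before,
            "posture_after_deg": m.posture_after,
            "truth_deg": m.posture_truth,
        }
        for m in metrics
        if m.posture_before is not None
    ]
    table2 = outdir / "table2.csv"
    pd.DataFrame(
        posture_rows,
        columns=["subject", "side", "posture_before_deg", "posture_after_deg", "truth_deg"],
    ).to_csv(table2, index=False)

    report = {
        "seed": seed,
        "config_hash": config_hash(config),
        "subjects": {
            key: {
                "P": r.transfer.P.tolist(),
                "permutation": list(r.transfer.permutation),
                "signs": r.transfer.signs.tolist(),
                "eigenvalues_deg2": r.eigen.eigenvalues.tolist(),
                "variance_ratio": (
                    None
                    if np.any(np.isnan(r.eigen.variance_ratio))
                    else r.eigen.variance_ratio.tolist()
                ),
                "corrected_posture": (
                    None
                    if r.corrected_posture is None
                    else r.corrected_posture.tolist()
                ),
            }
            for key, r in results.items()
        },
    }
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2))
    return {"table1": table1, "table2": table2, "report": report_path}
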