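"""Reading and writing the package's on-disk formats.

Formats handled here:

* label masks — single-channel TIFF or PNG rasters with values
  0 = background, 1 = donor (EGFP+), 2 = host (EGFP-);
* basal paths — 2-column headerless CSV ``row,col`` (0-based, row-major);
* run tables — TSV with header ``source_id  label  length  start``;
* coverage tables — TSV with header ``animal_id  chimerism_pct  coverage_pct``;
* result files — TSV (one row per trace/fit) and schema-versioned JSON.

The 2D-to-1D reduction is explicit: a mask carries an ordered, 8-connected
basal path, either supplied alongside the image or auto-traced as the lower
boundary of the non-background region.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyTraceError, ValidationError

logger = logging.getLogger("epimosaic")

SCHEMA_VERSION = "1.0"

#: donor, EGFP-positive label
POS = "POS"
#: host, EGFP-negative label
NEG = "NEG"

_LABEL_TO_VALUE = {POS: 1, NEG: 2}
_VALUE_TO_LABEL = {1: POS, 2: NEG}

# fraction of background pixels on a basal path above which a warning is logged
BACKGROUND_WARN_FRACTION = 0.10


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LabelMask:
    """Integer-labelled raster of an immunofluorescence section.

    Parameters
    ----------
    pixels
        2D integer array; 0 = background, 1 = donor/EGFP+, 2 = host/EGFP-.
    basal_path
        Ordered ``(row, col)`` coordinates tracing the basal layer,
        0-based, consecutive points 8-connected.
    pixel_size_um
        Optional physical pixel size (micrometres per pixel).
    source_id
        Free-text section identifier.
    """

    pixels: np.ndarray
    basal_path: list[tuple[int, int]]
    pixel_size_um: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"label mask must be 2D, got shape {self.pixels.shape}"
            )
        bad = np.setdiff1d(np.unique(self.pixels), [0, 1, 2])
        if bad.size:
            raise ValidationError(
                "label mask contains values outside {0, 1, 2}: "
                + ", ".join(str(v) for v in bad)
            )
        n_rows, n_cols = self.pixels.shape
        path = [(int(r), int(c)) for r, c in self.basal_path]
        for i, (r, c) in enumerate(path):
            if not (0 <= r < n_rows and 0 <= c < n_cols):
                raise ValidationError(
                    f"basal_path[{i}] = ({r}, {c}) leaves the "
                    f"{n_rows}x{n_cols} raster"
                )
        for i in range(1, len(path)):
            r0, c0 = path[i - 1]
            r1, c1 = path[i]
            if max(abs(r1 - r0), abs(c1 - c0)) > 1:
                raise ValidationError(
                    f"basal_path points {i - 1} and {i} are not 8-connected: "
                    f"({r0}, {c0}) -> ({r1}, {c1})"
                )
        self.basal_path = path


@dataclass
class BasalTrace:
    """Ordered binary label sequence along the basal layer of one section.

    ``labels`` is a boolean array, ``True`` for donor (EGFP+) pixels.
    """

    labels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValidationError("trace must be a non-empty 1D label sequence")

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return len(self) - self.n_pos

    def label_names(self) -> list[str]:
        return [POS if v else NEG for v in self.labels]


@dataclass(frozen=True)
class RunSegment:
    """One maximal contiguous same-label region along the trace."""

    label: str
    length: int
    start: int = 0

    def __post_init__(self) -> None:
        if self.label not in (POS, NEG):
            raise ValidationError(f"run label must be POS or NEG, got {self.label!r}")
        if self.length < 1:
            raise ValidationError(f"run length must be >= 1, got {self.length}")


# ---------------------------------------------------------------------------
# label masks
# ---------------------------------------------------------------------------

def _read_raster(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile

            return np.asarray(tifffile.imread(path))
        from PIL import Image

        with Image.open(path) as img:
            return np.asarray(img)
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"cannot read label mask {path}: {exc}") from exc


def auto_trace_basal_path(pixels: np.ndarray) -> list[tuple[int, int]]:
    """Trace the basal layer as the deepest non-background pixel per column.

    Columns with no foreground are skipped.  Where the depth jumps by more
    than one row between adjacent columns, intermediate points are inserted
    in the new column so the returned path stays 8-connected (any background
    pixels among them are dropped later by the trace-extraction skip rule).
    """
    pixels = np.asarray(pixels)
    path: list[tuple[int, int]] = []
    for c in range(pixels.shape[1]):
        rows = np.flatnonzero(pixels[:, c] != 0)
        if rows.size == 0:
            continue
        r = int(rows[-1])
        if path:
            r_prev = path[-1][0]
            step = 1 if r > r_prev else -1
            for ri in range(r_prev + step, r, step):
                path.append((ri, c))
        path.append((r, c))
    return path


def read_basal_path(path_table: str | Path) -> list[tuple[int, int]]:
    """Read a 2-column headerless CSV of ``row,col`` coordinates."""
    df = pd.read_csv(path_table, header=None)
    if df.shape[1] != 2:
        raise ValidationError(
            f"basal path table {path_table} must have exactly 2 columns, "
            f"got {df.shape[1]}"
        )
    return [(int(r), int(c)) for r, c in df.itertuples(index=False)]


def read_label_mask(
    path: str | Path,
    path_table: str | Path | None = None,
    pixel_size_um: float | None = None,
    source_id: str | None = None,
) -> LabelMask:
    """Read a label mask from TIFF/PNG, with an optional basal-path CSV.

    Without ``path_table`` the basal path is auto-traced as the ordered
    lower boundary of the non-background region.
    """
    path = Path(path)
    pixels = _read_raster(path)
    if path_table is not None:
        basal_path = read_basal_path(path_table)
    else:
        basal_path = auto_trace_basal_path(pixels)
    return LabelMask(
        pixels=pixels,
        basal_path=basal_path,
        pixel_size_um=pixel_size_um,
        source_id=source_id if source_id is not None else path.stem,
    )


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    """Write the raster of a mask as single-channel TIFF or PNG."""
    path = Path(path)
    pixels = mask.pixels.astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, pixels)
    else:
        from PIL import Image

        Image.fromarray(pixels, mode="L").save(path)


def extract_basal_trace(mask: LabelMask) -> BasalTrace:
    """Sample the mask along its basal path into a binary trace.

    Background pixels on the path are skipped, never imputed; skipping more
    than 10% of the path logs a warning.  A path sampling only background
    raises :class:`EmptyTraceError`.
    """
    if not mask.basal_path:
        raise EmptyTraceError(f"mask {mask.source_id!r} has an empty basal path")
    rows, cols = zip(*mask.basal_path)
    values = mask.pixels[np.asarray(rows), np.asarray(cols)]
    kept = values != 0
    n_skipped = int((~kept).sum())
    if n_skipped == values.size:
        raise EmptyTraceError(
            f"basal path of mask {mask.source_id!r} samples only background"
        )
    if n_skipped > BACKGROUND_WARN_FRACTION * values.size:
        logger.warning(
            "skipped_pixels source_id=%s skipped=%d of %d path points "
            "(background on basal path)",
            mask.source_id,
            n_skipped,
            values.size,
        )
    return BasalTrace(labels=values[kept] == _LABEL_TO_VALUE[POS],
                      source_id=mask.source_id)


# ---------------------------------------------------------------------------
# run-length coding
# ---------------------------------------------------------------------------

def run_length_encode(trace: BasalTrace) -> list[RunSegment]:
    """Split a trace into its maximal same-label runs, in order."""
    x = trace.labels
    change = np.flatnonzero(np.diff(x)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [x.size]))
    return [
        RunSegment(label=POS if x[s] else NEG, length=int(e - s), start=int(s))
        for s, e in zip(starts, ends)
    ]


def run_length_decode(runs: Sequence[RunSegment], source_id: str = "") -> BasalTrace:
    """Exact inverse of :func:`run_length_encode`.

    Rejects adjacent runs with equal label (non-maximal encodings).
    """
    if not runs:
        raise ValidationError("cannot decode an empty run list")
    for prev, cur in zip(runs, runs[1:]):
        if prev.label == cur.label:
            raise ValidationError(
                f"adjacent runs share label {cur.label}: non-maximal encoding"
            )
    labels = np.concatenate(
        [np.full(r.length, r.label == POS, dtype=bool) for r in runs]
    )
    return BasalTrace(labels=labels, source_id=source_id)


# ---------------------------------------------------------------------------
# run tables
# ---------------------------------------------------------------------------

RUN_TABLE_COLUMNS = ["source_id", "label", "length", "start"]


def write_run_table(traces: Iterable[BasalTrace], path: str | Path) -> None:
    """Write one or more traces as a run table (TSV).

    Each trace starts with a run at ``start == 0``; readers use that to
    delimit traces, so several sections of the same animal coexist in one
    file.
    """
    rows = []
    for trace in traces:
        for run in run_length_encode(trace):
            rows.append((trace.source_id, run.label, run.length, run.start))
    df = pd.DataFrame(rows, columns=RUN_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_run_table(path: str | Path) -> list[BasalTrace]:
    """Read a run table back into traces (one per ``start == 0`` block)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RUN_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"run table {path} lacks columns: {', '.join(missing)}"
        )
    traces: list[BasalTrace] = []
    current: list[RunSegment] = []
    current_id = ""
    for row in df.itertuples(index=False):
        if int(row.start) == 0 and current:
            traces.append(run_length_decode(current, source_id=current_id))
            current = []
        current.append(
            RunSegment(label=str(row.label), length=int(row.length),
                       start=int(row.start))
        )
        current_id = str(row.source_id)
    if current:
        traces.append(run_length_decode(current, source_id=current_id))
    return traces


# ---------------------------------------------------------------------------
# coverage tables
# ---------------------------------------------------------------------------

COVERAGE_TABLE_COLUMNS = ["animal_id", "chimerism_pct", "coverage_pct"]


def write_coverage_table(records: Iterable, path: str | Path) -> None:
    """Write per-animal (chimerism %, coverage %) records as TSV."""
    rows = [
        (r.animal_id, _fmt(r.chimerism_pct), _fmt(r.coverage_pct))
        for r in records
    ]
    pd.DataFrame(rows, columns=COVERAGE_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_coverage_table(path: str | Path) -> "list":
    """Read a coverage table into :class:`~epimosaic.coverage.CoverageRecord`s."""
    from .coverage import CoverageRecord

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COVERAGE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"coverage table {path} lacks columns: {', '.join(missing)}"
        )
    return [
        CoverageRecord(
            animal_id=str(row.animal_id),
            chimerism_pct=float(row.chimerism_pct),
            coverage_pct=float(row.coverage_pct),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------

def _fmt(value) -> str:
    """Serialize a scalar with 6 significant digits for floats."""
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        return format(float(value), ".6g")
    return str(value)


def _result_row(result) -> dict:
    """Flatten a ContiguityResult or CoverageFit into an ordered dict."""
    from .contiguity import ContiguityResult
    from .coverage import CoverageFit

    if isinstance(result, ContiguityResult):
        return {
            "source_id": result.source_id,
            "n_pixels": result.n_pos + result.n_neg,
            "n_pos": result.n_pos,
            "n_neg": result.n_neg,
            "p_positive": result.composition.p_positive,
            "p_negative": result.composition.p_negative,
            "n_runs": result.n_runs,
            "max_run_pos": result.max_run_pos,
            "max_run_neg": result.max_run_neg,
            "total_log_prob": result.total_log_prob,
            "null_mean_runs": result.null_mean_runs,
            "null_var_runs": result.null_var_runs,
            "perm_statistic": result.perm_statistic,
            "perm_p_value": result.perm_p_value,
            "n_perm": result.n_perm,
            "seed": result.seed,
            "testable": result.testable,
        }
    if isinstance(result, CoverageFit):
        return {
            "c50_pct": result.c50_pct,
            "slope": result.slope,
            "residual_sd": result.residual_sd,
            "n_animals": result.n_animals,
            "ci_c50_lo": result.ci_c50[0],
            "ci_c50_hi": result.ci_c50[1],
            "n_boot": result.n_boot,
            "seed": result.seed,
            "method": result.method,
        }
    raise ValidationError(f"cannot serialize result of type {type(result).__name__}")


def write_results(results, path: str | Path, format: str = "tsv") -> None:
    """Write a collection of results as TSV (one row each) or nested JSON.

    Field order is deterministic and floats carry 6 significant digits, so
    a write -> read -> write cycle is byte-identical.
    """
    path = Path(path)
    if isinstance(results, pd.DataFrame):
        rows = [dict(row) for _, row in results.iterrows()]
    else:
        rows = [_result_row(r) for r in results]
    if format == "tsv":
        if rows:
            header = list(rows[0])
            lines = ["\t".join(header)]
            lines += ["\t".join(_fmt(row[k]) for k in header) for row in rows]
        else:
            lines = ["\t".join(_EMPTY_TSV_HEADER)]
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        payload = {
            "schema_version": SCHEMA_VERSION,
            "results": [
                {k: _json_value(v) for k, v in row.items()} for row in rows
            ],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValidationError(f"unknown result format {format!r}")


_EMPTY_TSV_HEADER = [
    "source_id", "n_pixels", "n_pos", "n_neg", "p_positive", "p_negative",
    "n_runs", "max_run_pos", "max_run_neg", "total_log_prob",
    "null_mean_runs", "null_var_runs", "perm_statistic", "perm_p_value",
    "n_perm", "seed", "testable",
]


def _json_value(value):
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer)):
        return int(value)
    if isinstance(value, (float, np.floating)):
        return float(format(float(value), ".6g"))
    return value


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back; numeric columns are parsed, text kept."""
    return pd.read_csv(path, sep="\t")
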