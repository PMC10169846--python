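"""File formats: trace text/binary containers, event tables, image stacks.

Traces travel as two-column delimited text (time_s, current_pa) with a
commented header carrying the recording metadata, or as a compact .npz
container with the same metadata. Events and calibration tables are CSV;
statistics are flat JSON; image stacks are multi-frame grayscale TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .trace_analysis import BlockadeEvent, CurrentTrace, EventStatistics
from .transport_models import PegCalibration

EVENT_COLUMNS = ["start_s", "dwell_ms", "i0_pa", "ib_pa", "blockade_frac"]


def write_trace_txt(path: str | Path, trace: CurrentTrace,
                    seed: int | None = None, extra_header: dict | None = None) -> None:
    """Two-column text trace with commented metadata header."""
    header_items = {
        "sampling_rate_hz": trace.sampling_rate,
        "potential_mv": trace.applied_potential_mv,
    }
    if seed is not None:
        header_items["seed"] = seed
    if extra_header:
        header_items.update(extra_header)
    header = "\n".join(f"{k} = {v}" for k, v in header_items.items())
    data = np.column_stack([trace.times, trace.samples])
    np.savetxt(path, data, fmt="%.6f %.4f", header=header)


def read_trace_txt(path: str | Path) -> CurrentTrace:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line.lstrip("# ").split("=", 1)
                meta[k.strip()] = v.strip()
    data = np.loadtxt(path)
    return CurrentTrace(
        samples=data[:, 1],
        sampling_rate=float(meta.get("sampling_rate_hz", 0) or 1.0),
        applied_potential_mv=float(meta.get("potential_mv", 0.0)),
        label=str(Path(path)),
    )


def write_trace_npz(path: str | Path, trace: CurrentTrace,
                    seed: int | None = None) -> None:
    """Compact self-describing binary container (NumPy .npz)."""
    np.savez_compressed(
        path,
        samples_pa=trace.samples,
        sampling_rate_hz=trace.sampling_rate,
        potential_mv=trace.applied_potential_mv,
        seed=-1 if seed is None else seed,
    )


def read_trace_npz(path: str | Path) -> CurrentTrace:
    with np.load(path) as z:
        return CurrentTrace(
            samples=z["samples_pa"],
            sampling_rate=float(z["sampling_rate_hz"]),
            applied_potential_mv=float(z["potential_mv"]),
            label=str(Path(path)),
        )


def read_trace(path: str | Path) -> CurrentTrace:
    """Dispatch on extension: .npz binary, anything else delimited text."""
    return read_trace_npz(path) if str(path).endswith(".npz") else read_trace_txt(path)


def events_to_frame(events: list[BlockadeEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_s": e.start_time_s,
                "dwell_ms": e.dwell_ms,
                "i0_pa": e.baseline_pa,
                "ib_pa": e.mean_blocked_current_pa,
                "blockade_frac": e.blockade_fraction,
            }
            for e in events
        ],
        columns=EVENT_COLUMNS,
    )


def write_events_csv(path: str | Path, events: list[BlockadeEvent],
                     header_comment: str | None = None) -> None:
    frame = events_to_frame(events)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False, float_format="%.6g")


def read_events_csv(path: str | Path) -> list[BlockadeEvent]:
    frame = pd.read_csv(path, comment="#")
    return [
        BlockadeEvent(
            start_time_s=row.start_s,
            dwell_ms=row.dwell_ms,
            mean_blocked_current_pa=row.ib_pa,
            baseline_pa=row.i0_pa,
            blockade_fraction=row.blockade_frac,
        )
        for row in frame.itertuples()
    ]


def write_statistics_json(path: str | Path, stats: EventStatistics,
                          extra: dict | None = None) -> None:
    payload = {
        "n_events": stats.n_events,
        "duration_s": stats.duration_s,
        "capture_rate_per_min": stats.capture_rate_per_min,
        "blockade_mean": stats.blockade_mean,
        "blockade_sd": stats.blockade_sd,
        "dwell_mean_ms": stats.dwell_mean_ms,
        "blockade_hist_counts": stats.blockade_hist[0].tolist(),
        "blockade_hist_edges": stats.blockade_hist[1].tolist(),
        "dwell_hist_counts": stats.dwell_hist[0].tolist(),
        "dwell_hist_edges": stats.dwell_hist[1].tolist(),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_peg_calibration_csv(path: str | Path) -> PegCalibration:
    """Calibration table CSV with columns mw_da, dh_nm, blockade_frac."""
    frame = pd.read_csv(path, comment="#")
    return PegCalibration(
        mw_da=tuple(frame["mw_da"]),
        dh_nm=tuple(frame["dh_nm"]),
        blockade_frac=tuple(frame["blockade_frac"]),
    )


def write_image_stack_tiff(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def read_image_stack_tiff(path: str | Path) -> np.ndarray:
    stack = tifffile.imread(path)
    return stack[None] if stack.ndim == 2 else stack
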