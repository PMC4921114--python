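"""SPARKY .list 3D NOESY peak-list reader/writer.

Rows carry an optional assignment label, three shift columns and an
intensity column.  The axis convention is (H attached to the heavy atom,
heavy atom, other H); ``axis_order`` permutes file columns into that
convention.
"""

from __future__ import annotations

from pathlib import Path

from .types import CrossPeak, PeakList

_IDENTITY = (0, 1, 2)


def read_peak_list(
    path: str | Path,
    spectrum_kind: str,
    axis_order: tuple[int, int, int] = _IDENTITY,
) -> PeakList:
    """Read a SPARKY-style .list peak file.

    Rows with the wrong column count or a non-positive intensity are
    skipped with a warning and counted; surviving peaks keep file order.
    """
    rows_read = rows_kept = rows_skipped = 0
    warnings: list[str] = []
    peaks: list[CrossPeak] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if fields[0].lower() == "assignment":  # SPARKY header
            continue
        rows_read += 1
        label: str | None = None
        if fields and not _is_number(fields[0]):
            label = fields[0]
            fields = fields[1:]
        if len(fields) < 4:
            warnings.append(f"line {lineno}: expected 3 shifts + intensity, got {len(fields)} numeric fields")
            rows_skipped += 1
            continue
        try:
            w = [float(fields[0]), float(fields[1]), float(fields[2])]
            intensity = float(fields[3])
        except ValueError:
            warnings.append(f"line {lineno}: non-numeric field")
            rows_skipped += 1
            continue
        if intensity <= 0:
            warnings.append(f"line {lineno}: non-positive intensity {intensity}")
            rows_skipped += 1
            continue
        shifts = (w[axis_order[0]], w[axis_order[1]], w[axis_order[2]])
        peaks.append(CrossPeak(shifts=shifts, intensity=intensity,
                               spectrum_kind=spectrum_kind, id=rows_kept,
                               assignment_hint=label))
        rows_kept += 1
    if rows_read != rows_kept + rows_skipped:
        raise AssertionError("peak-list row counters do not reconcile")
    return PeakList(peaks=peaks, spectrum_kind=spectrum_kind,
                    rows_read=rows_read, rows_kept=rows_kept,
                    rows_skipped=rows_skipped, warnings=warnings)


def write_peak_list(peak_list: PeakList, path: str | Path) -> None:
    lines = ["      Assignment         w1         w2         w3   Data Height"]
    for p in peak_list.peaks:
        label = p.assignment_hint or "?-?-?"
        lines.append(f"{label:>16} {p.shifts[0]:10.3f} {p.shifts[1]:10.3f} "
                     f"{p.shifts[2]:10.3f} {p.intensity:14.6e}")
    Path(path).write_text("\n".join(lines) + "\n")


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True
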