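"""Plain-text readers/writers for the series containers.

* Keypoints: TRC (tab-delimited marker trajectory format, mm, with the
  standard DataRate/NumFrames/NumMarkers header). Invalid samples are written
  as empty cells, the usual convention for dropped markers.
* Orientations: a simple CSV dialect with columns time, segment, w, x, y, z.
* Joint angles: a tab-delimited STO-like table (time column plus named degree
  channels) with ``key=value`` header lines carrying rate and trial metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .series import JointAngleTable, KeypointSeries, OrientationSeries

__all__ = [
    "write_trc",
    "read_trc",
    "write_orientation_csv",
    "read_orientation_csv",
    "write_angle_table",
    "read_angle_table",
]

_FMT = "%.8g"


def write_trc(path, kp: KeypointSeries) -> None:
    path = Path(path)
    n, m = kp.points.shape[:2]
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{kp.rate:g}\t{kp.rate:g}\t{n}\t{m}\tmm\t{kp.rate:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(kp.names) + "\t\t",
        "\t\t"
        + "\t".join(f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(m)),
        "",
    ]
    rows = []
    for i in range(n):
        cells = [str(i + 1), _FMT % kp.times[i]]
        for j in range(m):
            if kp.valid[i, j]:
                cells.extend(_FMT % v for v in kp.points[i, j])
            else:
                cells.extend(["", "", ""])
        rows.append("\t".join(cells))
    path.write_text("\n".join(lines + rows) + "\n")


def read_trc(path) -> KeypointSeries:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 7:
        raise ParameterError("not a TRC file (too short)")
    hdr = lines[2].split("\t")
    rate = float(hdr[0])
    n_frames = int(hdr[2])
    n_markers = int(hdr[3])
    names = [c for c in lines[3].split("\t")[2:] if c]
    if len(names) != n_markers:
        raise ParameterError("TRC marker-name count disagrees with header")
    times = np.empty(n_frames)
    points = np.zeros((n_frames, n_markers, 3))
    valid = np.ones((n_frames, n_markers), dtype=bool)
    data_rows = [ln for ln in lines[5:] if ln.strip()]
    if len(data_rows) != n_frames:
        raise ParameterError("TRC frame count disagrees with header")
    for i, ln in enumerate(data_rows):
        cells = ln.split("\t")
        times[i] = float(cells[1])
        for j in range(n_markers):
            trio = cells[2 + 3 * j : 5 + 3 * j]
            if any(c == "" for c in trio):
                valid[i, j] = False
            else:
                points[i, j] = [float(c) for c in trio]
    return KeypointSeries(times=times, names=tuple(names), points=points, valid=valid, rate=rate)


def write_orientation_csv(path, ors: OrientationSeries) -> None:
    lines = [f"# rate_hz={ors.rate:g}", "time,segment,w,x,y,z"]
    for i, t in enumerate(ors.times):
        for j, seg in enumerate(ors.segments):
            w, x, y, z = (float(v) for v in ors.quats[i, j])
            lines.append(f"{float(t)!r},{seg},{w!r},{x!r},{y!r},{z!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_orientation_csv(path) -> OrientationSeries:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# rate_hz="):
        raise ParameterError("missing rate header in orientation CSV")
    rate = float(lines[0].split("=", 1)[1])
    recs: dict[float, dict[str, np.ndarray]] = {}
    segments: list[str] = []
    for ln in lines[2:]:
        if not ln.strip():
            continue
        t, seg, w, x, y, z = ln.split(",")
        q = np.array([float(w), float(x), float(y), float(z)])
        recs.setdefault(float(t), {})[seg] = q
        if seg not in segments:
            segments.append(seg)
    times = np.array(sorted(recs))
    quats = np.empty((len(times), len(segments), 4))
    for i, t in enumerate(times):
        for j, seg in enumerate(segments):
            quats[i, j] = recs[t][seg]
    return OrientationSeries(times=times, segments=tuple(segments), quats=quats, rate=rate)


def write_angle_table(path, table: JointAngleTable) -> None:
    meta = {
        k: v
        for k, v in table.meta.items()
        if isinstance(v, (str, int, float, bool))
    }
    names = list(table.channels)
    lines = [
        "armkin_angles",
        "version=1",
        f"rate_hz={table.rate:g}",
        f"meta={json.dumps(meta, sort_keys=True)}",
        f"nRows={len(table)}",
        f"nColumns={len(names) + 2}",
        "endheader",
        "\t".join(["time"] + names + ["gimbal_flag"]),
    ]
    for i in range(len(table)):
        row = [repr(float(table.times[i]))]
        row += [repr(float(table.channels[ch][i])) for ch in names]
        row.append(str(int(table.gimbal_flag[i])))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_angle_table(path) -> JointAngleTable:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != "armkin_angles":
        raise ParameterError("not an armkin angle table")
    meta: dict = {}
    rate = None
    i = 1
    while i < len(lines) and lines[i] != "endheader":
        key, _, val = lines[i].partition("=")
        if key == "rate_hz":
            rate = float(val)
        elif key == "meta":
            meta = json.loads(val)
        i += 1
    if rate is None:
        raise ParameterError("missing rate_hz header")
    header = lines[i + 1].split("\t")
    names = header[1:-1]
    data = np.array(
        [[float(c) for c in ln.split("\t")] for ln in lines[i + 2 :] if ln.strip()]
    )
    channels = {ch: data[:, 1 + j] for j, ch in enumerate(names)}
    return JointAngleTable(
        times=data[:, 0],
        rate=rate,
        channels=channels,
        meta=meta,
        gimbal_flag=data[:, -1].astype(bool),
    )
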