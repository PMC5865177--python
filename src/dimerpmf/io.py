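"""Text formats: XVG-style series, TSV tables, key-value configs.

Column layout of a window-series file (whitespace separated, '#' and '@'
lines are comments/legends):

    time_ps   d_nm   l   window_id   replica_id

Every writer emits a '#' header carrying provenance (bias parameters,
config hash and seed when available) so any output file can be traced
back to the run that produced it.  Readers report malformed lines with
their line numbers and refuse files that contain no data at all.
"""

from __future__ import annotations

import configparser
import hashlib
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .dynamics import WindowSeries
from .errors import EmptySeriesError, FormatError, IntegrityError
from .pmf import PMFCurve
from .sampling import ExchangeLog, UmbrellaLadder, UmbrellaWindow

_XVG_COLUMNS = ("time_ps", "d_nm", "l", "window_id", "replica_id")


# ---------------------------------------------------------------------------
# XVG-style window series
# ---------------------------------------------------------------------------
def write_window_series(path, series: WindowSeries,
                        header_extra: Optional[dict] = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# window series, columns: {' '.join(_XVG_COLUMNS)}\n")
        if series.bias_center is not None:
            fh.write(f"# bias_center_nm = {series.bias_center!r}\n")
            fh.write(f"# bias_k_kjmol_nm2 = {series.bias_k_kjmol!r}\n")
        for k, v in (header_extra or {}).items():
            fh.write(f"# {k} = {v}\n")
        fh.write('@ title "umbrella window series"\n')
        fh.write('@ xaxis label "time (ps)"\n')
        for t, d, l, r in zip(series.times, series.d_values,
                              series.l_values, series.replica_id_at_t):
            fh.write(f"{t:.6f} {d:.17g} {l:.17g} {series.window_id} {r}\n")


def read_window_series(path) -> list[WindowSeries]:
    """Read one XVG file or a directory of them; sorted by window id."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.xvg"))
        if not files:
            raise FormatError(f"{path}: no .xvg files")
        out = []
        for f in files:
            out.extend(read_window_series(f))
        out.sort(key=lambda s: s.window_id)
        return out
    rows = []
    bias_center = bias_k = None
    with path.open() as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                if "bias_center_nm" in s:
                    bias_center = float(s.split("=")[1])
                elif "bias_k_kjmol_nm2" in s:
                    bias_k = float(s.split("=")[1])
                continue
            if s.startswith("@"):
                continue
            parts = s.split()
            if len(parts) < 5:
                raise FormatError(
                    f"{path}:{ln}: expected 5 columns "
                    f"({', '.join(_XVG_COLUMNS)}), got {len(parts)}"
                )
            try:
                rows.append((float(parts[0]), float(parts[1]), float(parts[2]),
                             int(parts[3]), int(parts[4])))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from None
    if not rows:
        raise EmptySeriesError(f"{path}: comments/legends only, no data rows")
    arr = np.array(rows)
    wids = np.unique(arr[:, 3].astype(int))
    out = []
    for w in wids:
        sel = arr[:, 3].astype(int) == w
        t = arr[sel, 0]
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise IntegrityError(f"{path}: non-monotonic time in window {w}")
        out.append(WindowSeries(
            window_id=int(w), times=t, d_values=arr[sel, 1],
            l_values=arr[sel, 2], replica_id_at_t=arr[sel, 4].astype(int),
            bias_center=bias_center, bias_k_kjmol=bias_k,
        ))
    return out


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------
def write_ladder(path, ladder: UmbrellaLadder) -> None:
    with Path(path).open("w") as fh:
        fh.write("# umbrella ladder: center_nm\tk_kjmol_nm2\n")
        fh.write(f"# init_mode = {ladder.init_mode}\n")
        for w in ladder.windows:
            fh.write(f"{w.center:.6f}\t{w.k_kjmol:.6f}\n")


def read_ladder(path) -> UmbrellaLadder:
    init_mode = "bound"
    windows = []
    with Path(path).open() as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                if "init_mode" in s:
                    init_mode = s.split("=")[1].strip()
                continue
            parts = s.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: expected center and k")
            windows.append(UmbrellaWindow(float(parts[0]), float(parts[1])))
    if not windows:
        raise EmptySeriesError(f"{path}: no ladder rows")
    return UmbrellaLadder(windows=windows, init_mode=init_mode)


def write_exchange_log(path, log: ExchangeLog) -> None:
    with Path(path).open("w") as fh:
        fh.write("# exchange log: time_ps\ti\tj\tdU_kT\taccepted\tuniform_draw\n")
        fh.write(f"# tau_ex_ps = {log.tau_ex}\n")
        fh.write(f"# n_windows = {log.n_windows}\n")
        fh.write(f"# pair_scheme = {log.pair_scheme}\n")
        for k in range(len(log)):
            fh.write(
                f"{log.times[k]:.6f}\t{log.pair_i[k]}\t{log.pair_j[k]}\t"
                f"{log.du_kt[k]:.10e}\t{int(log.accepted[k])}\t"
                f"{log.uniform_draw[k]:.10e}\n"
            )


def read_exchange_log(path) -> ExchangeLog:
    tau = np.inf
    n_windows = 0
    rows = []
    with Path(path).open() as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                if "tau_ex_ps" in s:
                    tau = float(s.split("=")[1])
                elif "n_windows" in s:
                    n_windows = int(s.split("=")[1])
                continue
            p = s.split()
            if len(p) < 6:
                raise FormatError(f"{path}:{ln}: expected 6 columns")
            rows.append((float(p[0]), int(p[1]), int(p[2]), float(p[3]),
                         bool(int(p[4])), float(p[5])))
    if not rows:
        raise EmptySeriesError(f"{path}: no exchange records")
    t, i, j, du, acc, u = map(np.array, zip(*rows))
    return ExchangeLog(times=t, pair_i=i.astype(int), pair_j=j.astype(int),
                       du_kt=du, accepted=acc.astype(bool), uniform_draw=u,
                       tau_ex=tau, n_windows=n_windows or int(j.max()) + 1)


def write_pmf(path, curve: PMFCurve, header_extra: Optional[dict] = None) -> None:
    with Path(path).open("w") as fh:
        fh.write("# PMF: d_nm\td_int_nm\tF_kJmol\tstderr_kJmol\n")
        fh.write(f"# zero_convention = {curve.zero_convention}\n")
        fh.write(f"# kT_kjmol = {curve.kT!r}\n")
        for k, v in {**curve.provenance, **(header_extra or {})}.items():
            if isinstance(v, (str, int, float, bool, tuple, list)):
                fh.write(f"# {k} = {v}\n")
        dint = curve.d_int if curve.d_int is not None else np.full_like(curve.d, np.nan)
        err = (curve.stderr_kjmol if curve.stderr_kjmol is not None
               else np.full_like(curve.d, np.nan))
        for d, di, f, e in zip(curve.d, dint, curve.f_kjmol, err):
            fh.write(f"{d:.6f}\t{di:.6f}\t{f:.10f}\t{e:.10f}\n")


def read_pmf(path) -> PMFCurve:
    kT = None
    zero = ""
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                if "kT_kjmol" in s:
                    kT = float(s.split("=")[1])
                elif "zero_convention" in s:
                    zero = s.split("=", 1)[1].strip()
                continue
            rows.append([float(x) for x in s.split()])
    if not rows:
        raise EmptySeriesError(f"{path}: no PMF rows")
    arr = np.array(rows)
    dint = arr[:, 1] if np.isfinite(arr[:, 1]).any() else None
    err = arr[:, 3] if np.isfinite(arr[:, 3]).any() else None
    return PMFCurve(d=arr[:, 0], f_kjmol=arr[:, 2], kT=kT or 2.494,
                    zero_convention=zero, stderr_kjmol=err, d_int=dint)


# ---------------------------------------------------------------------------
# flat key-value config with sections
# ---------------------------------------------------------------------------
def read_config(path) -> configparser.ConfigParser:
    cp = configparser.ConfigParser()
    read = cp.read(str(path))
    if not read:
        raise FormatError(f"config file {path} not found or unreadable")
    return cp


def config_hash(cp: configparser.ConfigParser) -> str:
    """Stable hash of the canonicalized config content."""
    items = []
    for section in sorted(cp.sections()):
        for key in sorted(cp[section]):
            items.append(f"{section}.{key}={cp[section][key]}")
    return hashlib.sha256("\n".join(items).encode()).hexdigest()[:16]
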