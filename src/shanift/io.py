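"""Readers and writers for the plain-text SAS profile dialect.

Input: 3-column whitespace-delimited ASCII (q, I, sigma) as written by
beamline pipelines, '#' comments and textual headers tolerated.  Output:
a 4-column ``.fit`` file (q, I_e, sigma, I_c) with the fitted parameters
in the header and the model extrapolated down to q = 0 (sentinel
sigma = 0 marks model-only rows), and a 3-column ``_pr.dat`` file with
the P(r) curve and its pointwise uncertainty.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .core import default_r_grid, evaluate_intensity, evaluate_pr
from .errors import ProfileError
from .fitting import ScatteringProfile
from .pipeline import FitRecord

__all__ = ["read_dat", "write_fit", "write_pr", "read_header"]

log = logging.getLogger(__name__)


def read_dat(path, strict: bool = True) -> ScatteringProfile:
    """Parse a 3-column ASCII scattering profile.

    Blank lines and lines starting with '#' or a non-numeric token are
    skipped (header text).  Rows must then supply at least three numeric
    columns; q must be strictly increasing.  With ``strict`` (the
    default), rows with q <= 0 or sigma <= 0 are a hard error; pass
    ``strict=False`` to re-read this package's own ``.fit`` output, whose
    extrapolated model rows carry q down to 0 with the sigma = 0 sentinel
    (those rows are dropped).
    """
    path = Path(path)
    q, I, s = [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks or toks[0].startswith("#"):
                continue
            try:
                first = float(toks[0])
            except ValueError:
                continue  # textual header line
            if len(toks) < 3:
                raise ProfileError(f"{path.name}:{ln}: fewer than 3 numeric columns")
            try:
                vals = [float(t) for t in toks[:3]]
            except ValueError as exc:
                raise ProfileError(f"{path.name}:{ln}: non-numeric field ({exc})")
            q.append(vals[0]); I.append(vals[1]); s.append(vals[2])
    if not q:
        raise ProfileError(f"{path.name}: no numeric data rows")
    q = np.array(q); I = np.array(I); s = np.array(s)
    if not strict:
        keep = (s > 0) & (q > 0)
        q, I, s = q[keep], I[keep], s[keep]
    if np.any(np.diff(q) <= 0):
        raise ProfileError(f"{path.name}: q values are not strictly increasing")
    bad = np.flatnonzero(s <= 0)
    if bad.size:
        raise ProfileError(f"{path.name}: non-positive sigma at data rows {bad.tolist()[:10]}")
    return ScatteringProfile(q=q, I=I, sigma=s)


def _fmt(x: float) -> str:
    return repr(float(x))


def _header_lines(record: FitRecord) -> list[str]:
    p = record.params
    f = record.fit
    lines = [
        "# shanift fit output",
        f"# Dmax: {_fmt(f.D)}",
        f"# alpha: {_fmt(f.alpha)}",
        f"# chi2: {_fmt(f.chi2)}",
        f"# n_max: {f.n_max}",
        f"# n_total: {f.n_total}",
        f"# I0: {_fmt(p.I0)} +- {_fmt(p.I0_err)}",
        f"# Rg: {_fmt(p.rg)} +- {_fmt(p.rg_err)}",
        f"# ravg: {_fmt(p.ravg)} +- {_fmt(p.ravg_err)}",
        f"# Q: {_fmt(p.q_inv)}",
        f"# Vp: {_fmt(p.vp)} +- {_fmt(p.vp_err)}",
        f"# Vc: {_fmt(p.vc)} +- {_fmt(p.vc_err)}",
        f"# lc: {_fmt(p.lc)} +- {_fmt(p.lc_err)}",
        f"# MW: {_fmt(p.mw)}",
    ]
    for key, val in record.provenance.items():
        lines.append(f"# provenance {key}: {val}")
    return lines


def read_header(path) -> dict:
    """Parse the parameter header of a ``.fit``/``_pr.dat`` file back into
    a dict of floats (errors under ``<name>_err``)."""
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            toks = line[1:].split()
            if len(toks) >= 2 and toks[0].endswith(":"):
                key = toks[0][:-1]
                try:
                    out[key] = float(toks[1])
                except ValueError:
                    continue
                if len(toks) >= 4 and toks[2] == "+-":
                    out[key + "_err"] = float(toks[3])
    return out


def write_fit(record: FitRecord, path, q_extra=None) -> Path:
    """Write the 4-column fit file (q, I_e, sigma, I_c).

    The experimental rows are preceded by model-only rows extrapolated
    down to q = 0 (first row exactly q = 0, I_c = I(0)), marked with the
    sigma = 0 sentinel and I_e set equal to I_c.  ``q_extra`` replaces the
    default extrapolation grid with a user-supplied set of q values below
    the experimental range.
    """
    path = Path(path)
    prof = record.profile
    qe = prof.q_win
    if q_extra is not None:
        q_low = np.asarray(q_extra, dtype=float)
        q_low = np.sort(q_low[q_low < qe[0]])
        if q_low.size == 0 or q_low[0] > 0:
            q_low = np.concatenate([[0.0], q_low])
    else:
        dq = float(np.median(np.diff(qe)))
        q_low = np.arange(0.0, qe[0] - 0.5 * dq, dq)
    I_low, _ = evaluate_intensity(record.fit.coeffs, q_low)
    I_c, _ = evaluate_intensity(record.fit.coeffs, qe)
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(record)) + "\n")
        fh.write("# columns: q I_e sigma I_c (sigma=0 rows are extrapolated model)\n")
        for qv, iv in zip(q_low, I_low):
            fh.write(f"{_fmt(qv)} {_fmt(iv)} {_fmt(0.0)} {_fmt(iv)}\n")
        for qv, ie, sv, ic in zip(qe, prof.I_win, prof.sigma_win, I_c):
            fh.write(f"{_fmt(qv)} {_fmt(ie)} {_fmt(sv)} {_fmt(ic)}\n")
    return path


def write_pr(record: FitRecord, path, n_points: int = 501) -> Path:
    """Write the 3-column P(r) file (r, P, sigma_P) on [0, D]."""
    path = Path(path)
    r = default_r_grid(record.fit.D, n_points)
    p, perr = evaluate_pr(record.fit.coeffs, r)
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(record)) + "\n")
        fh.write("# columns: r P(r) sigma_P\n")
        for rv, pv, ev in zip(r, p, perr):
            fh.write(f"{_fmt(rv)} {_fmt(pv)} {_fmt(ev)}\n")
    return path
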