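"""Readers and writers for charge sets: PQR and the plain ``xyzq`` format.

``xyzq`` is four whitespace-separated columns — x y z (Å) and q (e) — with
``#`` comments.  PQR is the whitespace-delimited ATOM/HETATM flavor with
per-atom charge and radius as the last two fields; the radius is parsed
but unused here.
"""

from __future__ import annotations

import numpy as np

from .multipoles import ChargeSet


def read_xyzq(path) -> ChargeSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            fields = body.split()
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 columns (x y z q), got {len(fields)}"
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field: {exc}") from None
    if not rows:
        raise ValueError(f"{path}: no charge records found")
    arr = np.asarray(rows)
    return ChargeSet(arr[:, 3], arr[:, :3], label=str(path))


def write_xyzq(cs: ChargeSet, path) -> None:
    """Deterministic fixed 9-decimal output, one ``x y z q`` row per charge."""
    with open(path, "w") as fh:
        fh.write(f"# xyzq: x y z in A, q in e; label={cs.label}\n")
        for q, (x, y, z) in zip(cs.q, cs.r):
            fh.write(f"{x:.9f} {y:.9f} {z:.9f} {q:.9f}\n")


def read_pqr(path) -> ChargeSet:
    """Read ATOM/HETATM records from a whitespace-delimited PQR file.

    The last five fields of each record are x, y, z, charge, radius;
    everything else (names, residue bookkeeping, optional chain id) is
    ignored.  Non-atom lines (REMARK, TER, ...) are skipped.
    """
    qs, rs = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0] not in ("ATOM", "HETATM"):
                continue
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: truncated atom record")
            try:
                x, y, z, charge, _radius = (float(f) for f in fields[-5:])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric coordinate/charge/radius field"
                ) from None
            qs.append(charge)
            rs.append([x, y, z])
    if not qs:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return ChargeSet(np.asarray(qs), np.asarray(rs), label=str(path))


def load_chargeset(path) -> ChargeSet:
    """Dispatch on extension: ``.pqr`` → PQR, anything else → xyzq."""
    if str(path).lower().endswith(".pqr"):
        return read_pqr(path)
    return read_xyzq(path)
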