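"""b-value / echo-time acquisition schemes and their CSV representation.

A scheme is an ordered table of (b, TE, n_averages) rows.  Row order is the
single source of truth mapping 4-D volume frames to (b, TE): frame ``i``
corresponds to row ``i`` (or to the block of ``n_averages`` frames for row
``i`` when repeats are stored un-averaged).

Two liver protocols are provided: a full 6 b-value x 5 TE exploratory grid
(protocol 1), and a clinical-style protocol with a 9 b-value series at the
minimum TE plus low-b samples at two longer TEs (protocol 2), together with
its time-reduced "minimal" subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemeEntry",
    "AcquisitionScheme",
    "SchemeFormatError",
    "protocol1",
    "protocol2",
    "protocol2_minimal",
    "read_scheme",
    "write_scheme",
]

MIN_B_VALUES_IVIM = 4


class SchemeFormatError(ValueError):
    """Raised when a scheme table violates the CSV contract."""


@dataclass(frozen=True)
class SchemeEntry:
    b: float          # s mm^-2
    TE: float         # ms
    n_averages: int = 1


@dataclass
class AcquisitionScheme:
    """Ordered list of (b, TE, n_averages) measurement specifications.

    ``TR_ms``, ``delta_ms`` (gradient duration) and ``Delta_ms`` (diffusion
    time) are informational metadata only; the signal models do not use
    them.
    """

    entries: list[SchemeEntry] = field(default_factory=list)
    TR_ms: float | None = None
    delta_ms: float | None = None
    Delta_ms: float | None = None

    def __post_init__(self) -> None:
        for i, e in enumerate(self.entries):
            if e.b < 0:
                raise SchemeFormatError(f"row {i}: negative b ({e.b})")
            if e.TE <= 0:
                raise SchemeFormatError(f"row {i}: TE must be > 0 ({e.TE})")
            if e.n_averages < 1:
                raise SchemeFormatError(
                    f"row {i}: n_averages must be >= 1 ({e.n_averages})"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AcquisitionScheme):
            return NotImplemented
        return self.entries == other.entries

    @property
    def b(self) -> np.ndarray:
        return np.array([e.b for e in self.entries], dtype=float)

    @property
    def TE(self) -> np.ndarray:
        return np.array([e.TE for e in self.entries], dtype=float)

    @property
    def n_averages(self) -> np.ndarray:
        return np.array([e.n_averages for e in self.entries], dtype=int)

    def unique_TEs(self) -> np.ndarray:
        return np.unique(self.TE)

    def unique_bs(self) -> np.ndarray:
        return np.unique(self.b)

    def subset(self, mask) -> "AcquisitionScheme":
        """New scheme keeping entries where ``mask`` is True (same order)."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (len(self),):
            raise ValueError("mask length must equal number of entries")
        return AcquisitionScheme(
            entries=[e for e, keep in zip(self.entries, mask) if keep],
            TR_ms=self.TR_ms,
            delta_ms=self.delta_ms,
            Delta_ms=self.Delta_ms,
        )

    def at_TE(self, TE: float, atol: float = 1e-9) -> "AcquisitionScheme":
        return self.subset(np.isclose(self.TE, TE, atol=atol))

    def supports_ivim(self) -> bool:
        return len(np.unique(self.b)) >= MIN_B_VALUES_IVIM

    def supports_t2ivim(self) -> bool:
        return self.supports_ivim() and len(self.unique_TEs()) >= 2


# --- named protocols -------------------------------------------------------

_P1_BS = (0.0, 50.0, 100.0, 150.0, 200.0, 250.0)
_P1_TES = (62.0, 72.0, 82.0, 92.0, 102.0)
_P2_BS_MAIN = (0.0, 10.0, 50.0, 100.0, 150.0, 200.0, 250.0, 400.0, 800.0)
_P2_TE_MAIN = 62.0
_P2_BS_EXTRA = (0.0, 10.0, 50.0)
_P2_TES_EXTRA = (80.0, 100.0)


def protocol1() -> AcquisitionScheme:
    """Full exploratory grid: b in {0..250} x TE in {62..102}, 30 entries.

    Five signal averages per combination; TR 4000 ms, delta 17.6 ms,
    Delta 24.0 ms.
    """
    entries = [
        SchemeEntry(b=b, TE=te, n_averages=5)
        for te in _P1_TES
        for b in _P1_BS
    ]
    return AcquisitionScheme(entries, TR_ms=4000.0, delta_ms=17.6,
                             Delta_ms=24.0)


def protocol2() -> AcquisitionScheme:
    """Clinical-style scheme: 9 b-values (0-800) at TE 62 ms plus b in
    {0, 10, 50} at TE 80 and 100 ms; 12 averages, 15 entries."""
    entries = [
        SchemeEntry(b=b, TE=_P2_TE_MAIN, n_averages=12) for b in _P2_BS_MAIN
    ]
    entries += [
        SchemeEntry(b=b, TE=te, n_averages=12)
        for te in _P2_TES_EXTRA
        for b in _P2_BS_EXTRA
    ]
    return AcquisitionScheme(entries, TR_ms=4000.0, delta_ms=16.0,
                             Delta_ms=20.2)


def protocol2_minimal() -> AcquisitionScheme:
    """Time-reduced subset of :func:`protocol2`: drops (b=10, TE=80) and
    (b=10, TE=100) and keeps only six repeats per combination."""
    full = protocol2()
    entries = [
        SchemeEntry(b=e.b, TE=e.TE, n_averages=6)
        for e in full.entries
        if not (e.b == 10.0 and e.TE in _P2_TES_EXTRA)
    ]
    return AcquisitionScheme(entries, TR_ms=full.TR_ms,
                             delta_ms=full.delta_ms, Delta_ms=full.Delta_ms)


# --- CSV round trip --------------------------------------------------------

_CSV_COLUMNS = ["b", "TE_ms", "n_averages"]


def write_scheme(scheme: AcquisitionScheme, path) -> None:
    """Write the scheme as a UTF-8 CSV with columns b, TE_ms, n_averages."""
    df = pd.DataFrame(
        {
            "b": scheme.b,
            "TE_ms": scheme.TE,
            "n_averages": scheme.n_averages,
        }
    )
    df.to_csv(path, index=False)


def read_scheme(path) -> AcquisitionScheme:
    """Read a scheme CSV written by :func:`write_scheme`.

    Raises :class:`SchemeFormatError` naming the offending row for missing
    columns or invalid values.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemeFormatError(
            f"scheme CSV {path} is missing columns: {', '.join(missing)}"
        )
    entries = []
    for i, row in df.iterrows():
        b, te, nav = float(row["b"]), float(row["TE_ms"]), int(row["n_averages"])
        if b < 0:
            raise SchemeFormatError(f"row {i}: negative b ({b})")
        if te <= 0:
            raise SchemeFormatError(f"row {i}: TE must be > 0 ({te})")
        if nav < 1:
            raise SchemeFormatError(f"row {i}: n_averages must be >= 1 ({nav})")
        entries.append(SchemeEntry(b=b, TE=te, n_averages=nav))
    return AcquisitionScheme(entries)
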