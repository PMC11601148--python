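"""Reading and writing the package's on-disk formats.

Scattering curves use the 2/3-column ASCII dialect common to small-angle
scattering software (whitespace-separated ``q I [sigma]`` rows, ``#``
comments).  Charge and titration curves are exported as CSV; fit reports
as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .charge import ChargeCurve
from .saxs_analysis import FitResult
from .saxs_models import ScatteringCurve
from .titration import ITCProfile, TitrationCurve
from .waxs import WAXSPeakSet

__all__ = [
    "read_scattering",
    "write_scattering",
    "write_charge_curve",
    "write_titration_csv",
    "write_fit_report",
    "write_peak_table",
]


def read_scattering(path, units: str | None = None) -> ScatteringCurve:
    """Parse a 2- or 3-column ASCII scattering file.

    Rows must be consistently 2 columns (q, I) or 3 (q, I, σ); a malformed
    or mixed-width row raises with its line number.
    """
    path = Path(path)
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            fields = text.replace(",", " ").split()
            try:
                values = [float(v) for v in fields]
            except ValueError:
                raise ValueError(f"{path.name}:{lineno}: non-numeric row {text!r}") from None
            if len(values) not in (2, 3):
                raise ValueError(
                    f"{path.name}:{lineno}: expected 2 or 3 columns, got {len(values)}"
                )
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise ValueError(
                    f"{path.name}:{lineno}: inconsistent column count "
                    f"({len(values)} vs {width})"
                )
            rows.append(values)
    if not rows:
        raise ValueError(f"{path.name}: no data rows")
    arr = np.asarray(rows, dtype=float)
    meta = {"source": str(path)}
    if units:
        meta["units"] = units
    return ScatteringCurve(
        q=arr[:, 0],
        i=arr[:, 1],
        sigma=arr[:, 2] if arr.shape[1] == 3 else None,
        metadata=meta,
    )


def write_scattering(curve: ScatteringCurve, path, header: str | None = None) -> None:
    """Write a curve as SasView-style ASCII (full double precision)."""
    path = Path(path)
    cols = [curve.q, curve.i] + ([curve.sigma] if curve.sigma is not None else [])
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# q I" + (" sigma" if curve.sigma is not None else "") + "\n")
        for row in zip(*cols):
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def write_charge_curve(curve: ChargeCurve, path) -> None:
    pd.DataFrame({"pH": curve.ph, "Z": curve.z}).to_csv(path, index=False)


def write_titration_csv(
    curve: TitrationCurve, path, profile: ITCProfile | None = None
) -> None:
    """CSV of (ratio, pH[, heat]); heat is NaN at ratio 0 (no injection yet)."""
    df = pd.DataFrame({"ratio": curve.base_ratio, "pH": curve.ph})
    if profile is not None:
        heat = np.full(curve.base_ratio.size, np.nan)
        heat[1:] = profile.heat
        df["heat"] = heat
    df.to_csv(path, index=False)


def write_fit_report(result: FitResult, path) -> None:
    report = {
        "params": result.params.as_dict(),
        "uncertainties": result.uncertainties,
        "reduced_chi2": result.reduced_chi2,
        "status": result.status,
        "fixed": list(result.fixed),
        "warnings": list(result.warnings),
    }
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def write_peak_table(peaks: WAXSPeakSet, path) -> None:
    pd.DataFrame(
        [
            {
                "q": p.q,
                "d_A": p.d,
                "amplitude": p.amplitude,
                "width": p.width,
                "order": p.order,
                "family": p.family,
            }
            for p in peaks
        ]
    ).to_csv(path, index=False)
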