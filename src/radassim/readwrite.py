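"""File formats: long-form CSV time courses, scheme tables, parameter files.

Conventions enforced at the I/O boundary: times in hours since the first
fraction, doses in Gy, confluence in [0, 1].  Time courses are stored in long
format (one row per observation: sample_id, time_h, confluence, scheme_id,
n0) with a companion scheme table (scheme_id, total_dose_gy, n_fractions,
interval_h); long format tolerates ragged sampling grids across wells.
Parameter sets are stored as flat ``key = value`` text with units in comments.
"""

from __future__ import annotations

import hashlib
import io
import warnings
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    GlobalParams,
    GrowthParams,
    Prediction,
    RadiationSchedule,
    TimeCourse,
    ValidationError,
    build_schedule,
)

__all__ = [
    "read_time_courses",
    "write_time_courses",
    "read_schemes",
    "write_schemes",
    "write_growth_params",
    "read_growth_params",
    "write_global_params",
    "read_global_params",
    "write_predictions",
    "config_hash",
]

_TC_COLUMNS = ["sample_id", "time_h", "confluence", "scheme_id", "n0"]
_SCHEME_COLUMNS = ["scheme_id", "total_dose_gy", "n_fractions", "interval_h"]


def config_hash(obj) -> str:
    """Short stable hash of a configuration object for output provenance."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# scheme tables
# --------------------------------------------------------------------------


def scheme_key(s: RadiationSchedule) -> str:
    interval = s.fraction_times[1] - s.fraction_times[0] if s.n_fractions > 1 else 24.0
    return f"{s.total_dose:g}Gy_x{s.n_fractions}"


def write_schemes(schedules: Mapping[str, RadiationSchedule], path: Union[str, Path]) -> None:
    rows = []
    for sid, s in schedules.items():
        interval = s.fraction_times[1] - s.fraction_times[0] if s.n_fractions > 1 else 24.0
        rows.append(
            {"scheme_id": sid, "total_dose_gy": s.total_dose,
             "n_fractions": s.n_fractions, "interval_h": interval}
        )
    pd.DataFrame(rows, columns=_SCHEME_COLUMNS).to_csv(path, index=False)


def read_schemes(path: Union[str, Path]) -> Dict[str, RadiationSchedule]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_SCHEME_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"scheme table {path}: missing columns {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        out[str(row.scheme_id)] = build_schedule(
            float(row.total_dose_gy), int(row.n_fractions), float(row.interval_h)
        )
    return out


# --------------------------------------------------------------------------
# time courses
# --------------------------------------------------------------------------


def write_time_courses(
    courses: Sequence[TimeCourse],
    path: Union[str, Path],
    scheme_path: Optional[Union[str, Path]] = None,
) -> None:
    schemes: Dict[str, RadiationSchedule] = {}
    rows = []
    for tc in courses:
        sid = "" if tc.schedule is None else scheme_key(tc.schedule)
        if tc.schedule is not None:
            schemes[sid] = tc.schedule
        for t, c in zip(tc.times, tc.confluence):
            rows.append(
                {"sample_id": tc.sample_id, "time_h": t, "confluence": c,
                 "scheme_id": sid, "n0": tc.seeding_density_n0}
            )
    pd.DataFrame(rows, columns=_TC_COLUMNS).to_csv(path, index=False)
    if scheme_path is not None:
        write_schemes(schemes, scheme_path)


def read_time_courses(
    path: Union[str, Path],
    scheme_path: Optional[Union[str, Path]] = None,
) -> List[TimeCourse]:
    """Parse the long-format CSV dialect, with per-row diagnostics on bad input."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        warnings.warn(f"{path}: no observations found", RuntimeWarning, stacklevel=2)
        return []
    missing = set(_TC_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    schemes = read_schemes(scheme_path) if scheme_path is not None else {}
    bad = df.index[(df.confluence < 0) | (df.confluence > 1)]
    if len(bad):
        # +2: header line and 1-based numbering
        raise ValidationError(
            f"{path}: confluence outside [0, 1] at line {int(bad[0]) + 2} "
            f"(sample {df.loc[bad[0], 'sample_id']!r}, value {df.loc[bad[0], 'confluence']})"
        )
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        times = grp.time_h.to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            row = grp.index[np.argmax(np.diff(times) <= 0) + 1]
            raise ValidationError(
                f"{path}: non-monotone times for sample {sid!r} at line {int(row) + 2}"
            )
        scheme_id = str(grp.scheme_id.iloc[0]) if not pd.isna(grp.scheme_id.iloc[0]) else ""
        schedule = None
        if scheme_id:
            if scheme_id not in schemes:
                raise ValidationError(
                    f"{path}: sample {sid!r} references unknown scheme {scheme_id!r}"
                )
            schedule = schemes[scheme_id]
        out.append(
            TimeCourse(
                sample_id=str(sid),
                times=times,
                confluence=grp.confluence.to_numpy(dtype=float),
                seeding_density_n0=float(grp.n0.iloc[0]),
                schedule=schedule,
            )
        )
    return out


def write_predictions(
    predictions: Mapping[str, Prediction], path: Union[str, Path], meta: Optional[Mapping] = None
) -> None:
    rows = []
    for sid, p in predictions.items():
        for k in range(len(p)):
            rows.append(
                {"sample_id": sid, "time_h": p.times[k], "median": p.median[k],
                 "lower": p.lower[k], "upper": p.upper[k],
                 "window_index": int(p.window_index[k])}
            )
    buf = io.StringIO()
    for key, val in (meta or {}).items():
        buf.write(f"# {key}: {val}\n")
    pd.DataFrame(rows).to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


# --------------------------------------------------------------------------
# parameter files (flat key = value text, units in comments)
# --------------------------------------------------------------------------


def _fmt(v) -> str:
    return repr(float(v))


def _write_kv(path: Union[str, Path], lines: List[str], meta: Optional[Mapping] = None) -> None:
    header = [f"# {k}: {v}" for k, v in (meta or {}).items()]
    Path(path).write_text("\n".join(header + lines) + "\n")


def _read_kv(path: Union[str, Path]) -> Dict[str, float]:
    out = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"{path}: malformed line {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        out[key] = float(val)
    return out


def write_growth_params(g: GrowthParams, path: Union[str, Path],
                        sd: Optional[GrowthParams] = None,
                        meta: Optional[Mapping] = None) -> None:
    lines = [
        f"kp = {_fmt(g.kp)}  # proliferation rate, 1/h",
        f"theta = {_fmt(g.theta)}  # carrying capacity, confluence fraction",
        f"allee = {_fmt(g.allee)}  # Allee constant, dimensionless",
    ]
    if sd is not None:
        lines += [f"sd_kp = {_fmt(sd.kp)}", f"sd_theta = {_fmt(sd.theta)}", f"sd_allee = {_fmt(sd.allee)}"]
    _write_kv(path, lines, meta)


def read_growth_params(path: Union[str, Path]) -> GrowthParams:
    kv = _read_kv(path)
    try:
        return GrowthParams(kp=kv["kp"], theta=kv["theta"], allee=kv["allee"])
    except KeyError as exc:
        raise ValidationError(f"{path}: missing growth parameter {exc}") from exc


def write_global_params(p: GlobalParams, path: Union[str, Path],
                        meta: Optional[Mapping] = None) -> None:
    def block(gp: GlobalParams, prefix: str = "") -> List[str]:
        lines = [
            f"{prefix}kacute_n = {_fmt(gp.kacute_n)}  # 1/h per unit confluence",
            f"{prefix}alpha_accum_n = {_fmt(gp.alpha_accum_n)}  # per unit confluence",
            f"{prefix}kaccum_d = {_fmt(gp.kaccum_d)}  # 1/(h^2 Gy)",
            f"{prefix}r = {_fmt(gp.r)}  # 1/h",
        ]
        for d, v in sorted(gp.kps_by_total_dose.items()):
            lines.append(f"{prefix}kps_{d:g} = {_fmt(v)}  # 1/h per unit confluence")
        return lines

    lines = block(p)
    if p.sigma is not None:
        lines += block(p.sigma, prefix="sigma_")
    _write_kv(path, lines, meta)


def read_global_params(path: Union[str, Path]) -> GlobalParams:
    kv = _read_kv(path)

    def block(prefix: str) -> Optional[GlobalParams]:
        try:
            base = {name: kv[prefix + name] for name in ("kacute_n", "alpha_accum_n", "kaccum_d", "r")}
        except KeyError:
            if prefix:
                return None
            raise ValidationError(f"{path}: incomplete global parameter file")
        kps = {
            float(key[len(prefix) + 4:]): val
            for key, val in kv.items()
            if key.startswith(prefix + "kps_") and (prefix or not key.startswith("sigma_"))
        }
        if not kps:
            raise ValidationError(f"{path}: no kps entries found")
        return GlobalParams(kps_by_total_dose=kps, **base)

    main = block("")
    sigma = block("sigma_")
    if sigma is not None:
        main = GlobalParams(
            kacute_n=main.kacute_n, alpha_accum_n=main.alpha_accum_n,
            kaccum_d=main.kaccum_d, r=main.r,
            kps_by_total_dose=main.kps_by_total_dose, sigma=sigma,
        )
    return main
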