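"""Tabular readers and writers for the pipeline's interchange formats.

All files are UTF-8 text with "." as the decimal point.  The delimiter is
chosen from the file extension: ``.tsv`` → tab, anything else → comma.
Output core-parameter tables carry ``# key: value`` header comment lines
recording provenance (version, seed, thresholds).
"""

from __future__ import annotations

import io as _io
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .datamodel import (
    CORE_PARAMETER_COLUMNS,
    CoreParameters,
    DryingRun,
    HabitatRank,
    LightCurve,
    PigmentMeasurement,
    SchemaError,
    ThallusSample,
    ValidationError,
)

PathLike = Union[str, Path]

GAS_EXCHANGE_COLUMNS = [
    "sample_id",
    "curve_index",
    "ppfd",
    "assim",
    "mass_before_mg",
    "mass_after_mg",
]

SAMPLE_COLUMNS = [
    "sample_id",
    "species_code",
    "site",
    "dry_mass_mg",
    "area_cm2",
    "full_wet_mass_mg",
]

PIGMENT_COLUMNS = ["sample_id", "a665", "a649", "extract_volume_ml", "dm_mg"]


def _sep_for(path: PathLike) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _read_table(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def read_gas_exchange_table(path: PathLike, samples: Dict[str, ThallusSample]) -> List[DryingRun]:
    """Read a long-format gas-exchange table into validated drying runs.

    One row per (sample, curve, PPFD step).  ``samples`` maps sample_id to
    its :class:`ThallusSample` metadata (from :func:`read_samples_table`).
    Malformed rows are reported with their sample/curve identity.
    """
    df = _read_table(path, GAS_EXCHANGE_COLUMNS)
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    runs: List[DryingRun] = []
    for sample_id, sample_rows in df.groupby("sample_id", sort=True):
        if sample_id not in samples:
            raise ValidationError(f"{path}: sample {sample_id!r} not in samples table")
        curves = []
        for curve_index, curve_rows in sample_rows.groupby("curve_index", sort=True):
            curve_rows = curve_rows.sort_values("ppfd")
            mb = curve_rows["mass_before_mg"].unique()
            ma = curve_rows["mass_after_mg"].unique()
            if len(mb) != 1 or len(ma) != 1:
                raise ValidationError(
                    f"sample {sample_id} curve {curve_index}: inconsistent bracketing masses"
                )
            try:
                curves.append(
                    LightCurve(
                        curve_index=int(curve_index),
                        ppfd_steps=curve_rows["ppfd"].tolist(),
                        assim=curve_rows["assim"].tolist(),
                        mass_before_mg=float(mb[0]),
                        mass_after_mg=float(ma[0]),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"sample {sample_id}: {exc}") from None
        runs.append(DryingRun(sample=samples[sample_id], curves=curves))
    return runs


def read_samples_table(path: PathLike) -> Dict[str, ThallusSample]:
    """Read the sample-metadata table; duplicate sample ids are rejected."""
    df = _read_table(path, SAMPLE_COLUMNS)
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate sample_id values {sorted(set(dupes))}")
    out: Dict[str, ThallusSample] = {}
    for _, row in df.iterrows():
        s = ThallusSample(
            sample_id=str(row["sample_id"]),
            species_code=str(row["species_code"]),
            site=str(row["site"]),
            dry_mass_mg=float(row["dry_mass_mg"]),
            area_cm2=float(row["area_cm2"]),
            full_wet_mass_mg=float(row["full_wet_mass_mg"]),
        )
        out[s.sample_id] = s
    return out


def write_gas_exchange_table(runs: Sequence[DryingRun], path: PathLike) -> None:
    """Write drying runs in the long single-table layout."""
    rows = []
    for run in runs:
        for curve in run.curves:
            for ppfd, assim in zip(curve.ppfd_steps, curve.assim):
                rows.append(
                    {
                        "sample_id": run.sample.sample_id,
                        "curve_index": curve.curve_index,
                        "ppfd": ppfd,
                        "assim": assim,
                        "mass_before_mg": curve.mass_before_mg,
                        "mass_after_mg": curve.mass_after_mg,
                    }
                )
    pd.DataFrame(rows, columns=GAS_EXCHANGE_COLUMNS).to_csv(
        path, sep=_sep_for(path), index=False
    )


def write_samples_table(samples: Sequence[ThallusSample], path: PathLike) -> None:
    pd.DataFrame([asdict(s) for s in samples], columns=SAMPLE_COLUMNS).to_csv(
        path, sep=_sep_for(path), index=False
    )


def write_core_parameters(
    params: Sequence[CoreParameters],
    path: PathLike,
    *,
    metadata: Optional[Dict[str, object]] = None,
    species_summary: bool = False,
) -> None:
    """Write a core-parameter table (TSV/CSV) with provenance header lines.

    Raises on an empty collection rather than producing an empty file.
    With ``species_summary`` a per-species mean ± SD block is appended as
    comment lines (informational only; round-trip reads ignore it).
    """
    params = list(params)
    if not params:
        raise ValueError("refusing to write an empty core-parameter table")
    sep = _sep_for(path)
    df = pd.DataFrame([asdict(p) for p in params], columns=CORE_PARAMETER_COLUMNS)
    meta = {"pipeline_version": __version__}
    meta.update(metadata or {})
    buf = _io.StringIO()
    for key, value in meta.items():
        buf.write(f"# {key}: {value}\n")
    buf.write(
        "# units: lcp/lsp µmol photons m-2 s-1; max_np/dr_max nmol g-1DM s-1; "
        "wc_mm mm precipitation equivalent; wc_pct % of dry mass; stm mg cm-2; "
        "whc_mm mm; chl µg per mg DM\n"
    )
    df.to_csv(buf, sep=sep, index=False)
    if species_summary:
        numeric = df.select_dtypes("number").columns
        summary = df.groupby("species_code")[list(numeric)].agg(["mean", "std"])
        for species, row in summary.iterrows():
            parts = ", ".join(
                f"{col}={row[(col, 'mean')]:.4g}±{row[(col, 'std')]:.4g}" for col in numeric
            )
            buf.write(f"# summary {species}: {parts}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_core_parameters(path: PathLike) -> List[CoreParameters]:
    df = _read_table(path, CORE_PARAMETER_COLUMNS)
    out = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in CORE_PARAMETER_COLUMNS}
        kwargs["sample_id"] = str(kwargs["sample_id"])
        kwargs["species_code"] = str(kwargs["species_code"])
        for flag in ("min_wc_censored", "max_wc_censored"):
            kwargs[flag] = bool(kwargs[flag])
        for opt in ("chl_a", "chl_ab"):
            if pd.isna(kwargs[opt]):
                kwargs[opt] = None
        out.append(CoreParameters(**kwargs))
    return out


def core_parameters_frame(params: Sequence[CoreParameters]) -> pd.DataFrame:
    """Convenience: core parameters as a DataFrame in canonical column order."""
    return pd.DataFrame([asdict(p) for p in params], columns=CORE_PARAMETER_COLUMNS)


def read_pigments_table(path: PathLike) -> List[PigmentMeasurement]:
    df = _read_table(path, PIGMENT_COLUMNS)
    return [
        PigmentMeasurement(
            sample_id=str(row["sample_id"]),
            a665=float(row["a665"]),
            a649=float(row["a649"]),
            extract_volume_ml=float(row["extract_volume_ml"]),
            dm_mg=float(row["dm_mg"]),
        )
        for _, row in df.iterrows()
    ]


def read_ranks_table(path: PathLike) -> List[HabitatRank]:
    df = _read_table(path, ["species_code", "rank"])
    return [
        HabitatRank(species_code=str(row["species_code"]), rank=int(row["rank"]))
        for _, row in df.iterrows()
    ]
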