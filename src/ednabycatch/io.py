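"""CSV / FASTA / FASTQ plumbing with provenance headers.

All tabular I/O is UTF-8 comma-separated CSV with a mandatory header row
and ``.`` decimals; fractions are written with 6 decimals.  Output files
carry ``#``-prefixed provenance comment lines (package version, seed,
config hash) so pipelines are reproducible byte for byte; readers skip
those lines.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from ednabycatch.calibration import CalibrationModel, CalibrationSample, model_from_text, model_to_text
from ednabycatch.landings import LandingDataset, MethodEstimate
from ednabycatch.qpcr import QPCRMeasurement

__all__ = [
    "provenance_header",
    "write_table",
    "read_table",
    "write_calibration_samples",
    "read_calibration_samples",
    "read_qpcr_wells",
    "read_landing_replicates",
    "read_method_estimates",
    "load_bundled_method_estimates",
    "save_model",
    "load_model",
    "write_reads_fasta",
    "read_reads",
]

FRACTION_COLUMNS = ("edna_fraction", "true_weight_fraction", "fraction", "se_fraction")


def config_hash(config: dict | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def provenance_header(seed: int | None = None, config: dict | None = None) -> str:
    from ednabycatch import __version__

    return (
        f"# ednabycatch v{__version__}\n"
        f"# seed={seed if seed is not None else 'none'} config_hash={config_hash(config)}\n"
    )


def write_table(
    df: pd.DataFrame, path, seed: int | None = None, config: dict | None = None
) -> None:
    """Write a CSV with a provenance header; fraction columns get 6 decimals."""
    df = df.copy()
    for col in df.columns:
        if col in FRACTION_COLUMNS:
            df[col] = df[col].map(lambda v: f"{v:.6f}" if pd.notna(v) else "")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(provenance_header(seed, config))
        df.to_csv(fh, index=False)


def read_table(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a CSV, skipping provenance comments; validate required columns."""
    df = pd.read_csv(path, comment="#")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


# --- calibration samples -------------------------------------------------


def write_calibration_samples(
    samples: list[CalibrationSample], path, seed: int | None = None, config: dict | None = None
) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "season": [s.season for s in samples],
            "water_type": [s.water_type for s in samples],
            "true_weight_fraction": [s.true_weight_fraction for s in samples],
            "edna_fraction": [s.edna_fraction for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    )
    write_table(df, path, seed=seed, config=config)


def read_calibration_samples(path) -> list[CalibrationSample]:
    df = read_table(
        path,
        required=("sample_id", "season", "water_type", "true_weight_fraction", "edna_fraction"),
    )
    bad = df[
        (df.true_weight_fraction <= 0)
        | (df.true_weight_fraction >= 1)
        | (df.edna_fraction < 0)
        | (df.edna_fraction > 1)
    ]
    if not bad.empty:
        lines = ", ".join(str(i + 2) for i in bad.index[:5])
        raise ValueError(f"{path}: fractions out of range at data line(s) {lines}")
    return [
        CalibrationSample(
            sample_id=str(r.sample_id),
            season=str(r.season),
            water_type=str(r.water_type),
            true_weight_fraction=float(r.true_weight_fraction),
            edna_fraction=float(r.edna_fraction),
            replicate=int(getattr(r, "replicate", 0) or 0),
        )
        for r in df.itertuples()
    ]


# --- qPCR ----------------------------------------------------------------


def read_qpcr_wells(
    path,
) -> tuple[list[QPCRMeasurement], dict[str, list[tuple[float, float]]]]:
    """Read a well-level qPCR export.

    Columns: sample_id, target, cq (empty = not detected), optional
    dilution_copies (set for standard-curve wells) and ipc_pass (internal
    positive control; failing wells are dropped).

    Returns
    -------
    (measurements, dilution_points)
        Sample measurements, and per-target dilution series (copies, cq)
        for standard-curve fitting.
    """
    df = read_table(path, required=("sample_id", "target", "cq"))
    if "ipc_pass" in df.columns:
        df = df[df.ipc_pass.fillna(True).astype(bool)]
    measurements: list[QPCRMeasurement] = []
    dilutions: dict[str, list[tuple[float, float]]] = {}
    for idx, row in df.iterrows():
        cq = None if pd.isna(row.cq) else float(row.cq)
        copies = row.get("dilution_copies")
        if copies is not None and pd.notna(copies):
            if cq is None:
                raise ValueError(f"{path}: line {idx + 2}: dilution well without a Cq")
            dilutions.setdefault(str(row.target), []).append((float(copies), cq))
        else:
            measurements.append(
                QPCRMeasurement(
                    sample_id=str(row.sample_id),
                    target_species=str(row.target),
                    cq=cq,
                    replicate_index=int(row.get("replicate", 0) or 0),
                )
            )
    return measurements, dilutions


# --- landings ------------------------------------------------------------


def read_landing_replicates(path) -> dict[str, LandingDataset]:
    """Read a landing replicate table into one LandingDataset per landing.

    Columns: landing_id, stream (ship|factory), sample_id (tank or
    discharge interval), replicate, edna_fraction, optional
    total_landed_weight and tank_weight.
    """
    df = read_table(path, required=("landing_id", "stream", "sample_id", "edna_fraction"))
    datasets: dict[str, LandingDataset] = {}
    for landing_id, group in df.groupby("landing_id"):
        ship: dict[str, list[float]] = {}
        factory: dict[str, list[float]] = {}
        tank_weights: dict[str, float] = {}
        total = None
        if "total_landed_weight" in group.columns and group.total_landed_weight.notna().any():
            total = float(group.total_landed_weight.dropna().iloc[0])
        for _, row in group.iterrows():
            stream = str(row.stream)
            if stream not in ("ship", "factory"):
                raise ValueError(f"{path}: unknown stream {stream!r} in landing {landing_id}")
            target = ship if stream == "ship" else factory
            target.setdefault(str(row.sample_id), []).append(float(row.edna_fraction))
            if "tank_weight" in group.columns and pd.notna(row.get("tank_weight")):
                tank_weights[str(row.sample_id)] = float(row.tank_weight)
        datasets[str(landing_id)] = LandingDataset(
            landing_id=str(landing_id),
            total_landed_weight=total,
            ship_samples={k: tuple(v) for k, v in ship.items()},
            factory_samples={k: tuple(v) for k, v in factory.items()},
            tank_weights=tank_weights or None,
        )
    return datasets


def read_method_estimates(path) -> list[MethodEstimate]:
    """Read a method-estimate table (landing_id, method, tonnes, se, fraction, n)."""
    df = read_table(path, required=("landing_id", "method", "bycatch_tonnes", "fraction"))
    out = []
    for _, row in df.iterrows():
        out.append(
            MethodEstimate(
                landing_id=str(row.landing_id),
                method=str(row.method),
                fraction=float(row.fraction) if pd.notna(row.fraction) else None,
                se_fraction=None,
                bycatch_tonnes=float(row.bycatch_tonnes) if pd.notna(row.bycatch_tonnes) else None,
                se_tonnes=float(row.se_tonnes)
                if "se_tonnes" in df.columns and pd.notna(row.se_tonnes)
                else None,
                n=int(row.n) if "n" in df.columns and pd.notna(row.n) else 0,
            )
        )
    return out


def load_bundled_method_estimates() -> list[MethodEstimate]:
    """The bundled transcription of the four-landing method-comparison table."""
    path = resources.files("ednabycatch.data") / "table2_landings.csv"
    with resources.as_file(path) as p:
        return read_method_estimates(p)


# --- model store ---------------------------------------------------------


def save_model(model: CalibrationModel, directory) -> Path:
    """Write a model to ``<dir>/<season>_<water_type>.model`` (flat text)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{model.season}_{model.water_type}.model"
    path.write_text(model_to_text(model), encoding="utf-8")
    return path


def load_model(directory, season: str, water_type: str) -> CalibrationModel:
    path = Path(directory) / f"{season}_{water_type}.model"
    if not path.exists():
        raise FileNotFoundError(
            f"no calibration model for season={season!r} water_type={water_type!r} in {directory}"
        )
    return model_from_text(path.read_text(encoding="utf-8"))


# --- sequences -----------------------------------------------------------


def write_reads_fasta(reads: list[tuple[str, str, str]], path) -> None:
    """Write (read_id, species, sequence) triples as FASTA."""
    with open(path, "w", encoding="utf-8") as fh:
        for read_id, species, seq in reads:
            fh.write(f">{read_id} true_species={species}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_reads(path, fmt: str | None = None):
    """Read FASTA or FASTQ (Phred+33) into ReadRecords; format from suffix."""
    from Bio import SeqIO

    from ednabycatch.metabarcoding import ReadRecord

    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [ReadRecord(read_id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]
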