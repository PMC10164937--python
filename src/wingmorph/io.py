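"""Readers and writers: TPS, landmark/outline CSV, FASTA, Newick, run config.

TPS is the community-standard landmark interchange format (LM / ID / SCALE /
IMAGE keyed records).  Coordinates are stored internally in millimetres;
SCALE, when present, is applied multiplicatively at read time.  Population
labels come from a sidecar CSV (authoritative) or from an id prefix fallback
``<population>_<specimen>``.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .datatypes import (
    Dataset,
    DatasetError,
    LandmarkConfiguration,
    OutlineContour,
    ParseError,
    SequenceSet,
    Specimen,
)

logger = logging.getLogger("wingmorph")

_KNOWN_TPS_KEYS = {"LM", "ID", "SCALE", "IMAGE"}


def _population_for(spec_id: str, sidecar: dict[str, str] | None) -> str:
    if sidecar is not None and spec_id in sidecar:
        return sidecar[spec_id]
    if "_" in spec_id:
        return spec_id.split("_", 1)[0]
    raise DatasetError(
        f"no population label for specimen {spec_id!r}: provide a sidecar CSV "
        "or use '<population>_<name>' ids"
    )


def read_population_csv(path: str | Path) -> dict[str, str]:
    """Sidecar mapping specimen id -> population (columns: specimen, population)."""
    df = pd.read_csv(path, dtype=str)
    if not {"specimen", "population"} <= set(df.columns):
        raise ParseError(f"{path}: sidecar needs 'specimen' and 'population' columns")
    return dict(zip(df["specimen"], df["population"]))


def read_tps(path: str | Path, populations: dict[str, str] | None = None) -> Dataset:
    """Parse a TPS file into a landmark :class:`Dataset`.

    Records are LM=k blocks of k whitespace-separated coordinate lines with
    optional ID=, SCALE= and IMAGE= fields.  Unknown keys are ignored with a
    logged warning (tolerant reader).
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    configs: list[LandmarkConfiguration] = []
    i, record = 0, 0
    while i < len(lines):
        if not lines[i]:
            i += 1
            continue
        if not lines[i].upper().startswith("LM="):
            raise ParseError(f"{path}: record {record + 1}: expected LM=, got {lines[i]!r}")
        record += 1
        try:
            k = int(lines[i].split("=", 1)[1])
        except ValueError as exc:
            raise ParseError(f"{path}: record {record}: bad LM count") from exc
        i += 1
        coords = []
        while i < len(lines) and len(coords) < k:
            if not lines[i]:
                break
            parts = lines[i].split()
            if len(parts) != 2 or "=" in lines[i]:
                break
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ParseError(f"{path}: record {record}: bad coordinate line {lines[i]!r}") from exc
            i += 1
        if len(coords) != k:
            raise ParseError(
                f"{path}: record {record}: LM={k} but found {len(coords)} coordinate lines"
            )
        spec_id, scale = f"rec{record}", None
        while i < len(lines) and lines[i] and "=" in lines[i]:
            key, _, val = lines[i].partition("=")
            key = key.strip().upper()
            if key == "LM":
                break
            if key == "ID":
                spec_id = val.strip()
            elif key == "SCALE":
                scale = float(val)
            elif key not in _KNOWN_TPS_KEYS:
                logger.warning("%s: record %d: ignoring unknown TPS key %r", path, record, key)
            i += 1
        arr = np.asarray(coords, dtype=float)
        if scale is not None:
            arr = arr * scale
        pop = _population_for(spec_id, populations)
        configs.append(LandmarkConfiguration(Specimen(spec_id, pop), arr))
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise DatasetError(f"{path}: inconsistent landmark counts across records: {sorted(ks)}")
    ds = Dataset.from_configurations(configs)
    ds.validate()
    return ds


def write_tps(dataset: Dataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in dataset.configurations:
            fh.write(f"LM={c.k}\n")
            for x, y in c.coords:
                fh.write(f"{float(x)!r} {float(y)!r}\n")
            fh.write(f"ID={c.specimen.id}\n")


def read_landmark_csv(path: str | Path) -> Dataset:
    """Long-format landmark table: specimen, population, landmark, x, y.

    Landmark indices are 1-based and must be complete 1..k per specimen;
    missing or duplicated (specimen, landmark) pairs reject the file.
    Round-trips bit-identically with :func:`write_landmark_csv` for decimal
    text (repr-precision floats).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"specimen", "population", "landmark", "x", "y"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}")
    if df.duplicated(subset=["specimen", "landmark"]).any():
        bad = df[df.duplicated(subset=["specimen", "landmark"], keep=False)]
        pairs = sorted(set(zip(bad["specimen"], bad["landmark"])))
        raise DatasetError(f"{path}: duplicated (specimen, landmark) pairs: {pairs}")
    ks = df.groupby("specimen")["landmark"].agg(["min", "max", "count"])
    k = int(ks["count"].iloc[0])
    configs = []
    for spec_id, sub in df.groupby("specimen", sort=False):
        sub = sub.sort_values("landmark")
        idx = sub["landmark"].to_numpy()
        if len(idx) != k or idx[0] != 1 or idx[-1] != k or len(set(idx)) != len(idx):
            raise DatasetError(
                f"{path}: specimen {spec_id!r}: landmark indices {list(idx)} "
                f"do not form 1..{k}"
            )
        pop = str(sub["population"].iloc[0])
        coords = sub[["x", "y"]].to_numpy(dtype=float)
        configs.append(LandmarkConfiguration(Specimen(str(spec_id), pop), coords))
    ds = Dataset.from_configurations(configs)
    ds.validate()
    return ds


def write_landmark_csv(dataset: Dataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["specimen", "population", "landmark", "x", "y"])
        for c in dataset.configurations:
            for j, (x, y) in enumerate(c.coords, start=1):
                w.writerow([c.specimen.id, c.specimen.population, j, repr(float(x)), repr(float(y))])


def read_outline_csv(path: str | Path) -> Dataset:
    """Outline table: specimen, population, outline_set, point, x, y."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"specimen", "population", "outline_set", "point", "x", "y"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}")
    configs = []
    for spec_id, sub in df.groupby("specimen", sort=False):
        sub = sub.sort_values("point")
        configs.append(
            OutlineContour(
                Specimen(str(spec_id), str(sub["population"].iloc[0])),
                sub[["x", "y"]].to_numpy(dtype=float),
                outline_set=str(sub["outline_set"].iloc[0]),
            )
        )
    ds = Dataset.from_configurations(configs)
    ds.validate()
    return ds


def write_outline_csv(dataset: Dataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["specimen", "population", "outline_set", "point", "x", "y"])
        for c in dataset.configurations:
            for j, (x, y) in enumerate(c.points, start=1):
                w.writerow([c.specimen.id, c.specimen.population, c.outline_set, j, repr(float(x)), repr(float(y))])


def read_fasta(path: str | Path, population_token: str = "|") -> SequenceSet:
    """Read FASTA; the population is the header field after ``population_token``.

    Headers without the token get population ``"unknown"``.  The returned set
    has ``aligned=False`` until :meth:`SequenceSet.check_aligned` is called.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if population_token in header:
            seq_id, pop = header.split(population_token, 1)
        else:
            seq_id, pop = header, "unknown"
        records.append((seq_id, pop, str(rec.seq).upper()))
    if not records:
        raise ParseError(f"{path}: empty FASTA")
    return SequenceSet(records=records)


def write_fasta(seqset: SequenceSet, path: str | Path, population_token: str = "|") -> None:
    with open(path, "w") as fh:
        for seq_id, pop, seq in seqset.records:
            fh.write(f">{seq_id}{population_token}{pop}\n{seq}\n")


def load_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: run config must be a YAML mapping")
    return cfg


def write_manifest(out_dir: str | Path, params: dict) -> Path:
    """Record every run's parameters and seed next to its outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "run_manifest.json"
    manifest.write_text(json.dumps(params, indent=2, sort_keys=True, default=str))
    return manifest
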