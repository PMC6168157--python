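"""Readers and writers for the plain-text formats the pipeline consumes.

Conventions: BED is 0-based half-open; chrom.sizes is the two-column
UCSC layout; gene signatures come as GMT; all tables are UTF-8 TSV/CSV
with header rows; nested summaries are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atac import GenomeDef, PeakSet
from .imaging import DaughterPairSignal
from .niche import CentroidSet
from .transcriptome import ExpressionMatrix, GeneSignature
from .transition import ConditionObservation
from .transplant import ChimerismRecord, ChimerismSeries

__all__ = [
    "read_bed", "write_bed", "read_gmt", "write_gmt", "read_chrom_sizes",
    "write_chrom_sizes", "read_imaging_csv", "write_imaging_csv",
    "read_chimerism_csv", "write_chimerism_csv", "read_centroid_csv",
    "write_centroid_csv", "read_observations_table", "write_observations_table",
    "read_expression", "write_expression", "read_peaksets", "write_peaksets",
    "write_json", "file_sha256",
]


class FormatError(ValueError):
    pass


def read_bed(path) -> list[tuple[str, int, int]]:
    """Parse a BED3+ file into sorted 0-based half-open intervals.

    Track/browser lines and '#' comments are skipped; malformed lines
    raise with the offending line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as err:
                raise FormatError(f"{path}:{lineno}: {err}") from None
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{lineno}: invalid interval "
                                  f"{chrom}:{start}-{end}")
            intervals.append((chrom, start, end))
    return sorted(intervals)


def write_bed(path, intervals) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in sorted(intervals):
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_gmt(path) -> list[GeneSignature]:
    """Parse a GMT file (name, description, members...); duplicate
    signature names are an error, duplicate members are deduplicated."""
    sigs, seen = [], set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, "
                                  "description and >= 1 member")
            name = parts[0]
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate signature {name!r}")
            seen.add(name)
            sigs.append(GeneSignature(name=name, genes=frozenset(parts[2:])))
    return sigs


def write_gmt(path, signatures: list[GeneSignature]) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, "na", *sorted(sig.genes)]) + "\n")


def read_chrom_sizes(path) -> GenomeDef:
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'name\\tlength'")
            sizes[parts[0]] = int(parts[1])
    return GenomeDef(sizes)


def write_chrom_sizes(path, genome: GenomeDef) -> None:
    with open(path, "w") as fh:
        for name, length in genome.sizes.items():
            fh.write(f"{name}\t{length}\n")


# --------------------------------------------------------------------------
# tabular modalities


def read_imaging_csv(path) -> list[DaughterPairSignal]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [DaughterPairSignal(pair_id=str(r.pair_id), condition=str(r.condition),
                               marker=str(r.marker), volume_a=float(r.volume_a),
                               volume_b=float(r.volume_b), phase=str(r.phase))
            for r in df.itertuples(index=False)]


def write_imaging_csv(path, pairs: list[DaughterPairSignal]) -> None:
    pd.DataFrame([vars(p) if not hasattr(p, "__dataclass_fields__") else
                  {k: getattr(p, k) for k in p.__dataclass_fields__}
                  for p in pairs]).to_csv(path, index=False, float_format="%.17g")


def read_chimerism_csv(path) -> list[ChimerismSeries]:
    """Tidy long format: mouse_id, pair_id, slot, condition, week,
    donor_percent, b_percent, t_percent, myeloid_percent[, engrafted]."""
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for (mouse, pid, slot, cond), sub in df.groupby(
            ["mouse_id", "pair_id", "slot", "condition"], sort=False):
        sub = sub.sort_values("week")
        recs = tuple(ChimerismRecord(week=int(r.week),
                                     donor_percent=float(r.donor_percent),
                                     b_percent=float(r.b_percent),
                                     t_percent=float(r.t_percent),
                                     myeloid_percent=float(r.myeloid_percent))
                     for r in sub.itertuples(index=False))
        engrafted = bool(sub["engrafted"].iloc[0]) if "engrafted" in sub else True
        out.append(ChimerismSeries(mouse_id=str(mouse), pair_id=str(pid),
                                   daughter_slot=str(slot), condition=str(cond),
                                   records=recs, engrafted=engrafted))
    return out


def write_chimerism_csv(path, series: list[ChimerismSeries]) -> None:
    rows = []
    for s in series:
        for r in s.records:
            rows.append({"mouse_id": s.mouse_id, "pair_id": s.pair_id,
                         "slot": s.daughter_slot, "condition": s.condition,
                         "week": r.week, "donor_percent": r.donor_percent,
                         "b_percent": r.b_percent, "t_percent": r.t_percent,
                         "myeloid_percent": r.myeloid_percent,
                         "engrafted": s.engrafted})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_centroid_csv(path) -> list[CentroidSet]:
    """(field_id, group, x, y, z) rows -> one CentroidSet per field; a
    (field_id, group, nn_distance) layout is detected and returned as a
    DataFrame instead (precomputed-distance mode)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "nn_distance" in df.columns:
        return df
    out = []
    for (fid, grp), sub in df.groupby(["field_id", "group"], sort=False):
        out.append(CentroidSet(points=sub[["x", "y", "z"]].to_numpy(float),
                               group=str(grp), field_id=str(fid)))
    return out


def write_centroid_csv(path, fields: list[CentroidSet]) -> None:
    rows = []
    for cs in fields:
        for x, y, z in cs.points:
            rows.append({"field_id": cs.field_id, "group": cs.group,
                         "x": x, "y": y, "z": z})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_observations_table(path) -> list[ConditionObservation]:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    return [ConditionObservation(label=str(r.label), p_polar=float(r.p_polar),
                                 n_pairs=int(r.n_pairs), k_asym=int(r.k_asym))
            for r in df.itertuples(index=False)]


def write_observations_table(path, obs: list[ConditionObservation]) -> None:
    pd.DataFrame([{"label": o.label, "p_polar": o.p_polar,
                   "n_pairs": o.n_pairs, "k_asym": o.k_asym}
                  for o in obs]).to_csv(path, sep="\t", index=False)


def read_expression(values_path, metadata_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, index_col=0)
    return ExpressionMatrix(values=values, metadata=metadata)


def write_expression(values_path, metadata_path, matrix: ExpressionMatrix) -> None:
    matrix.values.to_csv(values_path, sep="\t")
    matrix.metadata.to_csv(metadata_path)


def read_peaksets(bed_dir, meta_path) -> list[tuple[PeakSet, PeakSet]]:
    """One BED per cell (named <cell_id>.bed) plus a metadata TSV with
    cell_id, pair_id, slot, mapped_reads; returns (A, B) tuples."""
    meta = pd.read_csv(meta_path, sep="\t")
    cells = {}
    for r in meta.itertuples(index=False):
        intervals = tuple(read_bed(Path(bed_dir) / f"{r.cell_id}.bed"))
        cells[(str(r.pair_id), str(r.slot))] = PeakSet(
            cell_id=str(r.cell_id), pair_id=str(r.pair_id), slot=str(r.slot),
            intervals=intervals, mapped_reads=int(r.mapped_reads))
    pairs = []
    for pid in dict.fromkeys(meta["pair_id"].astype(str)):
        if (pid, "A") in cells and (pid, "B") in cells:
            pairs.append((cells[(pid, "A")], cells[(pid, "B")]))
    return pairs


def write_peaksets(bed_dir, meta_path, pairs: list[tuple[PeakSet, PeakSet]]) -> None:
    bed_dir = Path(bed_dir)
    bed_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for a, b in pairs:
        for ps in (a, b):
            write_bed(bed_dir / f"{ps.cell_id}.bed", ps.intervals)
            rows.append({"cell_id": ps.cell_id, "pair_id": ps.pair_id,
                         "slot": ps.slot, "mapped_reads": ps.mapped_reads})
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


# --------------------------------------------------------------------------


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonify(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
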