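"""Readers/writers for the text formats the pipeline touches.

Formats
-------
* contact pairs: whitespace-delimited ``chromA posA chromB posB`` (a
  simplified NCC dialect — only positions are consumed downstream);
* N3D-style structures: per-bead ``chrom start x y z [x y z ...]`` with one
  coordinate triple per model, 6-decimal precision;
* BED (0-based half-open, optional 5th intensity column) and bedGraph;
* dense TSV matrices and YAML run configs.

All parsers reject malformed input with the file and line number rather than
silently coercing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeAssembly

CONTACT_COLUMNS = ["chrom_a", "pos_a", "chrom_b", "pos_b"]


class ParseError(ValueError):
    pass


def canonicalize_contacts(contacts: pd.DataFrame, assembly: GenomeAssembly | None = None) -> pd.DataFrame:
    """Order each record so (chromA, posA) <= (chromB, posB) in genome order."""
    df = contacts.reset_index(drop=True).copy()
    if df.empty:
        return df
    if assembly is not None:
        order = {c: i for i, c in enumerate(assembly.names)}
        ka = df["chrom_a"].map(order)
        kb = df["chrom_b"].map(order)
    else:
        cats = sorted(set(df["chrom_a"]) | set(df["chrom_b"]))
        order = {c: i for i, c in enumerate(cats)}
        ka = df["chrom_a"].map(order)
        kb = df["chrom_b"].map(order)
    swap = (ka > kb) | ((ka == kb) & (df["pos_a"] > df["pos_b"]))
    swap = swap.to_numpy()
    for a, b in (("chrom_a", "chrom_b"), ("pos_a", "pos_b")):
        va, vb = df[a].to_numpy().copy(), df[b].to_numpy().copy()
        df.loc[swap, a] = vb[swap]
        df.loc[swap, b] = va[swap]
    return df


def _validate_contacts(df: pd.DataFrame, assembly: GenomeAssembly, path) -> None:
    known = set(assembly.names)
    bad = sorted((set(df["chrom_a"]) | set(df["chrom_b"])) - known)
    if bad:
        raise ParseError(f"{path}: unknown chromosomes {bad}")
    for chrom_col, pos_col in (("chrom_a", "pos_a"), ("chrom_b", "pos_b")):
        lengths = df[chrom_col].map(assembly.lengths)
        out = (df[pos_col] < 0) | (df[pos_col] >= lengths)
        if out.any():
            line = int(df.index[out][0]) + 1
            raise ParseError(f"{path}:{line}: position outside chromosome")


def read_contacts(path, assembly: GenomeAssembly | None = None) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            try:
                rows.append((parts[0], int(parts[1]), parts[2], int(parts[3])))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer position") from None
    df = pd.DataFrame(rows, columns=CONTACT_COLUMNS)
    if assembly is not None and not df.empty:
        _validate_contacts(df, assembly, path)
    return canonicalize_contacts(df, assembly)


def write_contacts(contacts: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in contacts.itertuples(index=False):
            fh.write(f"{row.chrom_a}\t{int(row.pos_a)}\t{row.chrom_b}\t{int(row.pos_b)}\n")


# ---------------------------------------------------------------------------
# Structure ensembles


class StructureEnsemble:
    """M replica models of one cell's genome as beads with xyz coordinates.

    ``coords`` has shape (M, n_beads, 3) in bead-radius units; the bead
    layout is given by parallel arrays ``chroms`` (labels) and ``starts``
    (bp), ordered by genome position, with a common ``bin_size``.
    """

    def __init__(self, chroms, starts, coords, bin_size):
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.coords = np.asarray(coords, dtype=float)
        self.bin_size = int(bin_size)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (M, n_beads, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble must contain at least one model")
        if self.coords.shape[1] != self.chroms.size or self.chroms.size != self.starts.size:
            raise ValueError("bead layout and coordinates disagree")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    def chrom_codes(self) -> np.ndarray:
        """Integer chromosome code per bead (order of first appearance)."""
        seen, codes = {}, np.empty(self.chroms.size, dtype=np.int64)
        for i, c in enumerate(self.chroms):
            codes[i] = seen.setdefault(c, len(seen))
        return codes


def write_structure(ensemble: StructureEnsemble, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#bin_size\t{ensemble.bin_size}\n")
        fh.write(f"#models\t{ensemble.n_models}\n")
        for b in range(ensemble.n_beads):
            coords = "\t".join(
                f"{v:.6f}" for m in range(ensemble.n_models) for v in ensemble.coords[m, b]
            )
            fh.write(f"{ensemble.chroms[b]}\t{int(ensemble.starts[b])}\t{coords}\n")


def read_structure(path) -> StructureEnsemble:
    bin_size = None
    n_models = None
    chroms, starts, rows = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                if key == "bin_size":
                    bin_size = int(value)
                elif key == "models":
                    n_models = int(value)
                continue
            parts = line.split()
            if len(parts) < 5 or (len(parts) - 2) % 3 != 0:
                raise ParseError(f"{path}:{lineno}: expected chrom start + 3 coords per model")
            m = (len(parts) - 2) // 3
            if n_models is None:
                n_models = m
            elif m != n_models:
                raise ParseError(
                    f"{path}:{lineno}: model count mismatch ({m} vs {n_models})"
                )
            chroms.append(parts[0])
            starts.append(int(parts[1]))
            try:
                rows.append([float(v) for v in parts[2:]])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from None
    if not rows:
        raise ParseError(f"{path}: empty structure file")
    if bin_size is None:
        raise ParseError(f"{path}: missing #bin_size header")
    arr = np.asarray(rows, dtype=float).reshape(len(rows), n_models, 3)
    return StructureEnsemble(chroms, starts, arr.transpose(1, 0, 2), bin_size)


# ---------------------------------------------------------------------------
# BED / bedGraph

BED_COLUMNS = ["chrom", "start", "end"]


def read_bed(path) -> pd.DataFrame:
    """BED intervals, optional 4th name and 5th intensity column."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer interval") from None
            if start < 0 or start >= end:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name = parts[3] if len(parts) > 3 else "."
            intensity = float(parts[4]) if len(parts) > 4 else np.nan
            rows.append((parts[0], start, end, name, intensity))
    return pd.DataFrame(rows, columns=BED_COLUMNS + ["name", "intensity"])


def write_bed(intervals: pd.DataFrame, path) -> None:
    if not intervals.empty and (intervals["start"] >= intervals["end"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            fields = [str(row.chrom), str(int(row.start)), str(int(row.end))]
            if hasattr(row, "name") and row.name is not None:
                fields.append(str(row.name))
                if hasattr(row, "intensity") and not pd.isna(row.intensity):
                    fields.append(f"{row.intensity:.6f}")
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph fields")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph record") from None
            if start < 0 or start >= end:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            rows.append((parts[0], start, end, value))
    return pd.DataFrame(rows, columns=BED_COLUMNS + ["value"])


def write_bedgraph(track: pd.DataFrame, path) -> None:
    if not track.empty and (track["start"] >= track["end"]).any():
        raise ValueError("bedGraph intervals must satisfy start < end")
    with open(path, "w") as fh:
        for row in track.itertuples(index=False):
            value = "nan" if pd.isna(row.value) else f"{row.value:.6f}"
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{value}\n")


# ---------------------------------------------------------------------------
# Matrices and configs


def write_matrix(matrix: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter="\t", fmt="%.6g")


def read_matrix(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def read_run_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: run config must be a mapping")
    return cfg


def write_run_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
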