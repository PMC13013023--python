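"""Reading, validating and writing SWC morphology reconstructions.

SWC is the de-facto text format for neuron and glia reconstructions: one
sample point per row, seven whitespace-separated columns ::

    sample_id  type_code  x  y  z  radius  parent_id

with ``#`` comment lines. ``parent_id`` is -1 for a root sample. Type codes
follow the usual convention (1 = soma, 2 = axon, 3/4 = dendrite, >=5 other
processes, including glia). Coordinates and radii are micrometres.

This module deliberately does not repair broken files: radii <= 0 or
dangling parents are hard errors, because silent repair would bias the
downstream daughter/parent radius ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SOMA_TYPE = 1

__all__ = [
    "SwcSample",
    "Reconstruction",
    "SwcParseError",
    "SwcStructureError",
    "EmptySelectionError",
    "read_swc",
    "write_swc",
    "validate_reconstruction",
]


class SwcParseError(ValueError):
    """A line of an SWC file could not be parsed."""


class SwcStructureError(ValueError):
    """The sample table violates SWC structural invariants."""


class EmptySelectionError(ValueError):
    """A type-code restriction left no non-soma samples."""


@dataclass(frozen=True)
class SwcSample:
    """One reconstruction sample point.

    Attributes
    ----------
    sample_id : int
        Positive, unique within a file. Standard files number from 1.
    type_code : int
        SWC structure type (1 soma, 2 axon, 3-4 dendrite, >=5 other).
    x, y, z : float
        Position in micrometres.
    radius : float
        Process radius in micrometres; strictly positive.
    parent_id : int
        ``-1`` for a root sample, otherwise the id of the sample this one
        connects back to.
    """

    sample_id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int


@dataclass
class Reconstruction:
    """An ordered collection of SWC samples for one cell.

    Invariants (enforced by :func:`_check_structure`): sample ids unique,
    every non-root parent resolves to a declared sample, the parent
    relation is acyclic, radii strictly positive. Multiple roots are
    allowed — NeuroMorpho-style files may hold several disconnected trees.
    """

    samples: list[SwcSample]
    cell_id: str
    label: str | None = None
    source: str | None = None

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def roots(self) -> list[SwcSample]:
        return [s for s in self.samples if s.parent_id == -1]

    def sample_index(self) -> dict[int, SwcSample]:
        return {s.sample_id: s for s in self.samples}

    def to_dataframe(self) -> pd.DataFrame:
        """Sample table as a DataFrame (columns in SWC column order)."""
        return pd.DataFrame(
            [
                (s.sample_id, s.type_code, s.x, s.y, s.z, s.radius, s.parent_id)
                for s in self.samples
            ],
            columns=["sample_id", "type_code", "x", "y", "z", "radius", "parent_id"],
        )


def _check_structure(samples: Sequence[SwcSample], cell_id: str) -> None:
    ids = [s.sample_id for s in samples]
    id_set = set(ids)
    if len(id_set) != len(ids):
        dupes = {i for i in ids if ids.count(i) > 1}
        raise SwcStructureError(f"{cell_id}: duplicate sample ids {sorted(dupes)}")
    parent = {}
    for s in samples:
        if s.sample_id <= 0:
            raise SwcStructureError(f"{cell_id}: non-positive sample id {s.sample_id}")
        if s.parent_id == s.sample_id:
            raise SwcStructureError(f"{cell_id}: sample {s.sample_id} is its own parent")
        if s.radius <= 0:
            raise SwcStructureError(
                f"{cell_id}: sample {s.sample_id} has non-positive radius {s.radius}"
            )
        if s.parent_id != -1 and s.parent_id not in id_set:
            raise SwcStructureError(
                f"{cell_id}: sample {s.sample_id} references undefined parent {s.parent_id}"
            )
        parent[s.sample_id] = s.parent_id
    if not any(p == -1 for p in parent.values()):
        raise SwcStructureError(f"{cell_id}: no root sample (parent_id == -1)")
    # acyclicity: walk every sample to a root, path-compressing as we go
    resolved: set[int] = set()
    for sid in parent:
        path = []
        cur = sid
        while cur != -1 and cur not in resolved:
            if cur in path:
                raise SwcStructureError(f"{cell_id}: cycle through sample {cur}")
            path.append(cur)
            cur = parent[cur]
        resolved.update(path)


def read_swc(path: str | Path, cell_id: str | None = None, label: str | None = None) -> Reconstruction:
    """Read and validate an SWC file.

    Parameters
    ----------
    path : str or Path
        File to read. ``#`` comment lines and blank lines are skipped.
    cell_id : str, optional
        Identifier for the cell; defaults to the file stem.
    label : str, optional
        Class label to attach (e.g. ``"astrocyte"``).

    Returns
    -------
    Reconstruction
        Validated reconstruction with sample order preserved.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    SwcParseError
        On a malformed line (wrong column count, non-numeric field); the
        message names the 1-based line number.
    SwcStructureError
        On duplicate ids, dangling parents, cycles or non-positive radii.
    """
    path = Path(path)
    if cell_id is None:
        cell_id = path.stem
    samples: list[SwcSample] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SwcParseError(
                    f"{path}:{lineno}: expected 7 columns, got {len(fields)}"
                )
            try:
                samples.append(
                    SwcSample(
                        sample_id=int(fields[0]),
                        type_code=int(fields[1]),
                        x=float(fields[2]),
                        y=float(fields[3]),
                        z=float(fields[4]),
                        radius=float(fields[5]),
                        parent_id=int(fields[6]),
                    )
                )
            except ValueError as exc:
                raise SwcParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
    _check_structure(samples, cell_id)
    logger.info("read %d samples from %s", len(samples), path)
    return Reconstruction(samples=samples, cell_id=cell_id, label=label, source=str(path))


def write_swc(rec: Reconstruction, path: str | Path) -> Path:
    """Write a reconstruction as a standard 7-column SWC file.

    Floats are written with ``repr`` (shortest round-tripping form) so that
    ``read_swc(write_swc(rec))`` reproduces the sample table exactly.
    An empty reconstruction is an error.
    """
    if not rec.samples:
        raise ValueError(f"{rec.cell_id}: refusing to write an empty reconstruction")
    _check_structure(rec.samples, rec.cell_id)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# cell_id: {rec.cell_id}\n")
        if rec.label is not None:
            fh.write(f"# label: {rec.label}\n")
        if rec.source is not None:
            fh.write(f"# source: {rec.source}\n")
        fh.write("# columns: id type x y z radius parent\n")
        for s in rec.samples:
            fh.write(
                f"{s.sample_id} {s.type_code} {float(s.x)!r} {float(s.y)!r} "
                f"{float(s.z)!r} {float(s.radius)!r} {s.parent_id}\n"
            )
    return path


def validate_reconstruction(
    rec: Reconstruction, structure_types: Iterable[int] | None = None
) -> Reconstruction:
    """Restrict a reconstruction to the given SWC structure types.

    Keeps samples whose ``type_code`` is in ``structure_types`` plus all
    soma samples (needed as branch roots); subtrees whose retained parent
    was removed are re-rooted (parent set to -1). ``structure_types=None``
    keeps every non-soma type present (the default analysis mode, since
    source datasets rarely state which codes were traced per cell class).

    Raises
    ------
    EmptySelectionError
        If no non-soma samples survive.
    """
    _check_structure(rec.samples, rec.cell_id)
    if structure_types is None:
        keep_types = {s.type_code for s in rec.samples}
    else:
        keep_types = set(structure_types) | {SOMA_TYPE}
    kept = [s for s in rec.samples if s.type_code in keep_types]
    kept_ids = {s.sample_id for s in kept}
    rerooted = 0
    out: list[SwcSample] = []
    for s in kept:
        if s.parent_id != -1 and s.parent_id not in kept_ids:
            out.append(replace(s, parent_id=-1))
            rerooted += 1
        else:
            out.append(s)
    n_removed = len(rec.samples) - len(out)
    if n_removed or rerooted:
        logger.info(
            "%s: removed %d samples outside types %s, re-rooted %d subtrees",
            rec.cell_id, n_removed, sorted(keep_types), rerooted,
        )
    if not any(s.type_code != SOMA_TYPE for s in out):
        raise EmptySelectionError(
            f"{rec.cell_id}: no non-soma samples with type codes {sorted(keep_types)}"
        )
    return Reconstruction(samples=out, cell_id=rec.cell_id, label=rec.label, source=rec.source)
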