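"""Read, write and merge SNP-array genotype panels in PLINK text PED/MAP format.

A :class:`GenotypePanel` is the container every analysis stage consumes: a
samples x markers matrix of diploid calls coded as the count of ``allele_b``
(0, 1 or 2), with :data:`MISSING` as a distinct code, plus a marker map and
per-sample breed labels.  Breed labels are supplied through a separate
two-column sample->breed table rather than the PED family column, which is
unreliable in practice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid call ("0 0" in PED).  Never conflated with
#: dosage 0 (homozygous allele_a).
MISSING: int = -1

#: Placeholder allele character for markers where only one allele was observed.
UNKNOWN_ALLELE: str = "0"


class PedFormatError(ValueError):
    """A PED/MAP file pair is malformed (e.g. column-count mismatch)."""


class BreedLabelError(KeyError):
    """A PED sample has no entry in the sample->breed lookup."""


class MergeConflictError(ValueError):
    """Shared markers whose allele pairs neither match nor swap."""

    def __init__(self, marker_ids: Sequence[str]):
        self.marker_ids = list(marker_ids)
        super().__init__(
            "irreconcilable allele coding for markers: "
            + ", ".join(self.marker_ids)
        )


@dataclass(frozen=True)
class MarkerInfo:
    """One biallelic marker on the map.

    ``position_bp`` is 1-based inclusive, as in MAP files.  ``allele_b`` is
    the counted allele; for markers where a second allele was never observed
    it holds :data:`UNKNOWN_ALLELE`.
    """

    marker_id: str
    chromosome: str
    position_bp: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.position_bp <= 0:
            raise ValueError(f"{self.marker_id}: position_bp must be positive")
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.marker_id}: allele_a == allele_b")


def _chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


@dataclass
class GenotypePanel:
    """Samples x markers diploid genotype matrix with breed labels.

    ``calls[i, j]`` is the count of ``markers[j].allele_b`` carried by sample
    ``i`` (0, 1, 2) or :data:`MISSING`.
    """

    markers: list[MarkerInfo]
    sample_ids: list[str]
    breeds: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )
        if len(self.breeds) != len(self.sample_ids):
            raise ValueError("one breed label per sample required")
        if any(not b for b in self.breeds):
            raise ValueError("breed labels must be non-empty")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_id in panel")
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker_id in panel")
        bad = self.calls[(self.calls != MISSING) & ((self.calls < 0) | (self.calls > 2))]
        if bad.size:
            raise ValueError("calls must be 0, 1, 2 or MISSING")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"marker {marker_id!r} not in panel") from None

    def breed_mask(self, breed: str) -> np.ndarray:
        mask = np.array([b == breed for b in self.breeds], dtype=bool)
        if not mask.any():
            raise KeyError(f"breed {breed!r} not in panel")
        return mask

    def breed_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for b in self.breeds:
            out[b] = out.get(b, 0) + 1
        return out

    def subset_markers(self, indices: Sequence[int]) -> "GenotypePanel":
        idx = np.asarray(indices, dtype=int)
        return GenotypePanel(
            markers=[self.markers[i] for i in idx],
            sample_ids=list(self.sample_ids),
            breeds=list(self.breeds),
            calls=self.calls[:, idx].copy(),
        )

    def subset_samples(self, indices: Sequence[int]) -> "GenotypePanel":
        idx = np.asarray(indices, dtype=int)
        return GenotypePanel(
            markers=list(self.markers),
            sample_ids=[self.sample_ids[i] for i in idx],
            breeds=[self.breeds[i] for i in idx],
            calls=self.calls[idx, :].copy(),
        )

    def canonicalized(self) -> "GenotypePanel":
        """Copy re-coded to the first-observed allele convention.

        PED files carry no allele-coding metadata, so :func:`read_ped_map`
        always labels the first allele observed in the file ``allele_a``.
        This method applies the same convention to an in-memory panel: a
        marker whose first non-missing call is homozygous ``allele_b`` has
        its coding flipped (alleles swapped, dosages ``2 - x``), and a marker
        where ``allele_b`` is never carried gets the unknown-allele
        placeholder.  ``write_ped_map`` then ``read_ped_map`` is the identity
        on canonical panels.
        """
        markers = list(self.markers)
        calls = self.calls.copy()
        for j, m in enumerate(markers):
            col = calls[:, j]
            obs = col[col != MISSING]
            if obs.size == 0:
                markers[j] = replace(m, allele_a="A", allele_b=UNKNOWN_ALLELE)
                continue
            if obs[0] == 2:  # allele_b seen first when written
                nonmiss = col != MISSING
                col[nonmiss] = 2 - col[nonmiss]
                markers[j] = replace(m, allele_a=m.allele_b, allele_b=m.allele_a)
                m = markers[j]
                obs = col[col != MISSING]
            if not (obs > 0).any() and m.allele_b != UNKNOWN_ALLELE:
                markers[j] = replace(m, allele_b=UNKNOWN_ALLELE)
        return GenotypePanel(markers, list(self.sample_ids), list(self.breeds),
                             calls)

    def sort_markers(self) -> "GenotypePanel":
        """Return a copy with markers sorted by (chromosome, position_bp)."""
        order = sorted(
            range(self.n_markers),
            key=lambda j: (
                _chrom_sort_key(self.markers[j].chromosome),
                self.markers[j].position_bp,
            ),
        )
        return self.subset_markers(order)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        return (
            self.markers == other.markers
            and self.sample_ids == other.sample_ids
            and self.breeds == other.breeds
            and np.array_equal(self.calls, other.calls)
        )


# -- PED/MAP I/O --------------------------------------------------------------


def read_breed_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, breed) TSV into a lookup dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "breed"],
                     dtype=str, comment="#")
    return dict(zip(df["sample_id"], df["breed"]))


def write_breed_tsv(panel: GenotypePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, breed in zip(panel.sample_ids, panel.breeds):
            fh.write(f"{sid}\t{breed}\n")


def read_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    breed_map: Mapping[str, str],
) -> GenotypePanel:
    """Parse a PLINK text PED/MAP pair into a :class:`GenotypePanel`.

    Per marker, ``allele_a`` is the first allele observed scanning PED rows
    top to bottom and ``allele_b`` the first observed allele that differs from
    it; a "0 0" genotype becomes :data:`MISSING`.  Marker order follows the
    MAP file.  Every PED sample must appear in ``breed_map``.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PedFormatError(
                    f"{map_path}: line {lineno}: expected 4 columns, got {len(parts)}"
                )
            chrom, marker_id, _cm, pos = parts
            map_rows.append((marker_id, chrom, int(pos)))
    n_markers = len(map_rows)

    sample_ids: list[str] = []
    breeds: list[str] = []
    raw: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise PedFormatError(
                    f"{ped_path}: row {lineno}: expected {6 + 2 * n_markers} "
                    f"columns for {n_markers} markers, got {len(parts)}"
                )
            sid = parts[1]
            if sid not in breed_map:
                raise BreedLabelError(
                    f"sample {sid!r} (row {lineno}) missing from breed table"
                )
            sample_ids.append(sid)
            breeds.append(breed_map[sid])
            alleles = parts[6:]
            raw.append([(alleles[2 * j], alleles[2 * j + 1]) for j in range(n_markers)])

    n_samples = len(sample_ids)
    calls = np.full((n_samples, n_markers), MISSING, dtype=np.int8)
    markers: list[MarkerInfo] = []
    for j, (marker_id, chrom, pos) in enumerate(map_rows):
        allele_a: str | None = None
        allele_b: str | None = None
        for i in range(n_samples):
            for a in raw[i][j]:
                if a == "0":
                    continue
                if allele_a is None:
                    allele_a = a
                elif allele_b is None and a != allele_a:
                    allele_b = a
        if allele_a is None:
            allele_a = "A"  # fully missing marker: arbitrary placeholder
        if allele_b is None:
            allele_b = UNKNOWN_ALLELE
        for i in range(n_samples):
            a1, a2 = raw[i][j]
            if a1 == "0" or a2 == "0":
                continue
            calls[i, j] = (a1 == allele_b) + (a2 == allele_b)
        markers.append(MarkerInfo(marker_id, chrom, pos, allele_a, allele_b))

    return GenotypePanel(markers, sample_ids, breeds, calls)


def write_ped_map(
    panel: GenotypePanel, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a panel as PLINK text PED/MAP.

    MISSING is written "0 0"; heterozygotes are order-normalised to
    ``allele_a allele_b``; the PED family column carries the breed label
    (readers ignore it).  Re-reading with the matching breed table reproduces
    the panel.
    """
    with open(map_path, "w") as fh:
        for m in panel.markers:
            fh.write(f"{m.chromosome}\t{m.marker_id}\t0\t{m.position_bp}\n")
    geno_strings = {
        0: lambda m: f"{m.allele_a} {m.allele_a}",
        1: lambda m: f"{m.allele_a} {m.allele_b}",
        2: lambda m: f"{m.allele_b} {m.allele_b}",
        MISSING: lambda m: "0 0",
    }
    with open(ped_path, "w") as fh:
        for i, (sid, breed) in enumerate(zip(panel.sample_ids, panel.breeds)):
            fields = [breed, sid, "0", "0", "0", "-9"]
            for j, m in enumerate(panel.markers):
                fields.append(geno_strings[int(panel.calls[i, j])](m))
            fh.write(" ".join(fields) + "\n")


# -- merging ------------------------------------------------------------------


def _reconcile(m1: MarkerInfo, m2: MarkerInfo) -> bool | None:
    """True if panel-2 dosages must be flipped, False if not, None if conflict.

    An :data:`UNKNOWN_ALLELE` allele_b (monomorphic source) acts as a wildcard
    against the other source's coding.  Alleles that neither match nor swap —
    including apparent strand flips — are conflicts, not guesses.
    """
    a1, b1, a2, b2 = m1.allele_a, m1.allele_b, m2.allele_a, m2.allele_b
    if a2 == a1 and (b2 == b1 or b2 == UNKNOWN_ALLELE or b1 == UNKNOWN_ALLELE):
        return False
    if a2 == b1 and (b2 == a1 or b2 == UNKNOWN_ALLELE):
        return True
    if b2 == a1 and a2 == b1:
        return True
    if b1 == UNKNOWN_ALLELE and b2 == a1:
        # source 1 monomorphic for what source 2 calls allele_b
        return True
    return None


def merge_panels(panel_1: GenotypePanel, panel_2: GenotypePanel) -> GenotypePanel:
    """Merge two panels over their shared markers, reconciling allele coding.

    Markers are matched by ``marker_id`` (intersection); where the second
    source codes the alleles in swapped order its dosages are flipped
    (``2 - x``, MISSING preserved) so that ``allele_b`` means the same allele
    in the merged panel.  Samples are concatenated; a sample present in both
    inputs is an error.
    """
    overlap = set(panel_1.sample_ids) & set(panel_2.sample_ids)
    if overlap:
        raise ValueError(f"samples present in both panels: {sorted(overlap)}")

    idx2 = {m.marker_id: j for j, m in enumerate(panel_2.markers)}
    shared = [(j1, idx2[m.marker_id]) for j1, m in enumerate(panel_1.markers)
              if m.marker_id in idx2]

    conflicts: list[str] = []
    keep1: list[int] = []
    keep2: list[int] = []
    flips: list[bool] = []
    merged_markers: list[MarkerInfo] = []
    for j1, j2 in shared:
        m1, m2 = panel_1.markers[j1], panel_2.markers[j2]
        flip = _reconcile(m1, m2)
        if flip is None:
            conflicts.append(m1.marker_id)
            continue
        keep1.append(j1)
        keep2.append(j2)
        flips.append(flip)
        # prefer a concretely observed allele_b over the unknown placeholder
        if m1.allele_b == UNKNOWN_ALLELE and m2.allele_b != UNKNOWN_ALLELE:
            b = m2.allele_b if not flip else m2.allele_a
            merged_markers.append(replace(m1, allele_b=b))
        else:
            merged_markers.append(m1)
    if conflicts:
        raise MergeConflictError(conflicts)

    calls1 = panel_1.calls[:, keep1]
    calls2 = panel_2.calls[:, keep2].copy()
    flip_arr = np.asarray(flips, dtype=bool)
    if flip_arr.any():
        cols = calls2[:, flip_arr]
        nonmiss = cols != MISSING
        cols[nonmiss] = 2 - cols[nonmiss]
        calls2[:, flip_arr] = cols

    merged = GenotypePanel(
        markers=merged_markers,
        sample_ids=panel_1.sample_ids + panel_2.sample_ids,
        breeds=panel_1.breeds + panel_2.breeds,
        calls=np.vstack([calls1, calls2]),
    )
    return merged.sort_markers()
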