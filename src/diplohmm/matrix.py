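"""Reads-by-sites allele matrix.

The central data structure is the alignment matrix M: rows are sequencing
reads, columns are candidate variant sites.  Entry (i, j) is the allele the
read supports at site j (an index into the column's allele set) or a gap,
meaning the read provides no information there.  Each non-gap entry carries a
phred-scaled confidence weight.

Columns are 0-based internally; VCF input/output converts to 1-based.
"""

from __future__ import annotations

import io
import warnings
from typing import Iterable, Sequence

import numpy as np

GAP = -1  #: gap code in the entries array


class AlignmentMatrixError(ValueError):
    pass


class AlignmentMatrix:
    """Allele matrix M with per-entry phred weights.

    Parameters
    ----------
    entries:
        (m, n) integer array; ``GAP`` (-1) marks gaps, other values index
        into ``site_alleles[j]``.
    weights:
        (m, n) non-negative phred-scaled confidences; must be 0 exactly at
        gaps and > 0 elsewhere.
    site_positions:
        strictly increasing reference coordinates (0-based), length n.
    site_alleles:
        per-column allele tuple ``Sigma_j`` (first allele is the reference
        allele by convention).
    read_ids:
        m stable read identifiers.
    """

    def __init__(
        self,
        entries: np.ndarray,
        weights: np.ndarray,
        site_positions: Sequence[int],
        site_alleles: Sequence[tuple[str, ...]],
        read_ids: Sequence[str],
        *,
        _allow_empty: bool = False,
    ) -> None:
        self.entries = np.asarray(entries, dtype=np.int16)
        self.weights = np.asarray(weights, dtype=np.float64)
        self.site_positions = np.asarray(site_positions, dtype=np.int64)
        self.site_alleles = [tuple(a) for a in site_alleles]
        self.read_ids = list(read_ids)
        self._validate(allow_empty=_allow_empty)
        gap = self.entries == GAP
        any_cov = ~gap
        m, n = self.entries.shape
        self._first = np.where(any_cov.any(axis=1), np.argmax(any_cov, axis=1), n)
        self._last = np.where(
            any_cov.any(axis=1), n - 1 - np.argmax(any_cov[:, ::-1], axis=1), -1
        )

    # -- basic shape ------------------------------------------------------
    @property
    def m(self) -> int:
        return self.entries.shape[0]

    @property
    def n(self) -> int:
        return self.entries.shape[1]

    def _validate(self, allow_empty: bool = False) -> None:
        if self.entries.ndim != 2:
            raise AlignmentMatrixError("entries must be 2-dimensional")
        m, n = self.entries.shape
        if self.weights.shape != (m, n):
            raise AlignmentMatrixError("weights shape mismatch")
        if len(self.site_positions) != n or len(self.site_alleles) != n:
            raise AlignmentMatrixError("site metadata length mismatch")
        if len(self.read_ids) != m:
            raise AlignmentMatrixError("read_ids length mismatch")
        if n > 1 and not np.all(np.diff(self.site_positions) > 0):
            raise AlignmentMatrixError("site_positions must be strictly increasing")
        gap = self.entries == GAP
        if np.any(self.weights < 0):
            raise AlignmentMatrixError("weights must be non-negative")
        if np.any(self.weights[gap] != 0):
            raise AlignmentMatrixError("gap entries must have weight 0")
        if np.any(self.weights[~gap] <= 0):
            raise AlignmentMatrixError("non-gap entries must have weight > 0")
        for j, sigma in enumerate(self.site_alleles):
            col = self.entries[:, j]
            bad = (col != GAP) & ((col < 0) | (col >= len(sigma)))
            if np.any(bad):
                raise AlignmentMatrixError(f"entry outside allele set at column {j}")
        if not allow_empty:
            if m == 0 or n == 0:
                raise AlignmentMatrixError("empty matrix")
            if np.any(gap.all(axis=1)):
                raise AlignmentMatrixError("all-gap row")
            if np.any(gap.all(axis=0)):
                raise AlignmentMatrixError("all-gap column")

    # -- active / terminal rows ------------------------------------------
    def _check_column(self, j: int) -> None:
        if not 0 <= j < self.n:
            raise IndexError(f"column index {j} out of range [0, {self.n})")

    def first_nongap(self, i: int) -> int:
        return int(self._first[i])

    def last_nongap(self, i: int) -> int:
        return int(self._last[i])

    def active_rows(self, j: int) -> frozenset[int]:
        """Rows whose covered interval [first, last] contains column j.

        A row with an internal gap at j is still active there.
        """
        self._check_column(j)
        sel = (self._first <= j) & (self._last >= j)
        return frozenset(np.flatnonzero(sel).tolist())

    def active_nonterminal_rows(self, j: int) -> frozenset[int]:
        """Active rows whose last non-gap entry lies strictly after column j."""
        self._check_column(j)
        sel = (self._first <= j) & (self._last > j)
        return frozenset(np.flatnonzero(sel).tolist())

    def max_coverage(self) -> int:
        """max_j |A_j|: the largest number of rows active at any column."""
        depth = np.zeros(self.n, dtype=int)
        for i in range(self.m):
            if self._first[i] <= self._last[i]:
                depth[self._first[i] : self._last[i] + 1] += 1
        return int(depth.max())

    def column_depths(self) -> np.ndarray:
        """Per-column count of non-gap entries."""
        return (self.entries != GAP).sum(axis=0)

    # -- row-set manipulation --------------------------------------------
    def take_rows(self, rows: Iterable[int], *, allow_empty_columns: bool = False) -> "AlignmentMatrix":
        rows = sorted(rows)
        return AlignmentMatrix(
            self.entries[rows],
            self.weights[rows],
            self.site_positions,
            self.site_alleles,
            [self.read_ids[i] for i in rows],
            _allow_empty=allow_empty_columns,
        )

    def cut_reads(self, max_variants_per_fragment: int) -> "AlignmentMatrix":
        """Cut every read into fragments covering at most k consecutive sites.

        Chunking is greedy left-to-right over each row's covered columns.
        Fragment ids record the parent read (``<read_id>/0``, ``/1``, ...).
        The multiset of non-gap entries is conserved.
        """
        k = max_variants_per_fragment
        if k < 1:
            raise ValueError("max_variants_per_fragment must be >= 1")
        new_entries, new_weights, new_ids = [], [], []
        for i in range(self.m):
            covered = np.flatnonzero(self.entries[i] != GAP)
            chunks = [covered[s : s + k] for s in range(0, len(covered), k)]
            if len(chunks) == 1:
                new_entries.append(self.entries[i])
                new_weights.append(self.weights[i])
                new_ids.append(self.read_ids[i])
                continue
            for c, cols in enumerate(chunks):
                e = np.full(self.n, GAP, dtype=np.int16)
                w = np.zeros(self.n)
                e[cols] = self.entries[i, cols]
                w[cols] = self.weights[i, cols]
                new_entries.append(e)
                new_weights.append(w)
                new_ids.append(f"{self.read_ids[i]}/{c}")
        return AlignmentMatrix(
            np.array(new_entries),
            np.array(new_weights),
            self.site_positions,
            self.site_alleles,
            new_ids,
        )

    def downsample(self, target_coverage: float, seed: int) -> "AlignmentMatrix":
        """Random read subset with expected mean column depth ``target_coverage``.

        Reads are kept independently (without replacement) with probability
        target/current where current is the mean non-gap depth.  Deterministic
        under a fixed seed.  If the target is at or above the current
        coverage the matrix is returned unchanged with a warning.
        """
        if target_coverage <= 0:
            raise ValueError("target_coverage must be > 0")
        current = float(self.column_depths().mean())
        if target_coverage >= current:
            warnings.warn(
                f"target coverage {target_coverage} >= current {current:.2f}; "
                "returning input unchanged"
            )
            return self
        rng = np.random.default_rng(seed)
        keep = np.flatnonzero(rng.random(self.m) < target_coverage / current)
        # never return an unusable empty matrix
        if len(keep) == 0:
            keep = np.array([int(rng.integers(self.m))])
        kept_cols = (self.entries[keep] != GAP).any(axis=0)
        if not kept_cols.all():
            # re-add, per uncovered column, one random read covering it
            for j in np.flatnonzero(~kept_cols):
                cands = np.flatnonzero(self.entries[:, j] != GAP)
                keep = np.union1d(keep, [int(rng.choice(cands))])
        return self.take_rows(keep)

    # -- text dialect -----------------------------------------------------
    def to_text(self) -> str:
        """Serialize to the tab-separated test dialect (lossless round-trip)."""
        out = io.StringIO()
        out.write("##positions=" + ",".join(map(str, self.site_positions)) + "\n")
        out.write(
            "##alleles=" + ",".join("|".join(a) for a in self.site_alleles) + "\n"
        )
        for i in range(self.m):
            fields = [self.read_ids[i]]
            for j in range(self.n):
                if self.entries[i, j] == GAP:
                    fields.append("-")
                else:
                    allele = self.site_alleles[j][self.entries[i, j]]
                    fields.append(f"{allele}:{self.weights[i, j]:g}")
            out.write("\t".join(fields) + "\n")
        return out.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "AlignmentMatrix":
        positions: list[int] = []
        alleles: list[tuple[str, ...]] = []
        entries, weights, ids = [], [], []
        for line in text.splitlines():
            if not line.strip():
                continue
            if line.startswith("##positions="):
                positions = [int(x) for x in line.split("=", 1)[1].split(",")]
            elif line.startswith("##alleles="):
                alleles = [
                    tuple(a.split("|")) for a in line.split("=", 1)[1].split(",")
                ]
            else:
                fields = line.rstrip("\n").split("\t")
                ids.append(fields[0])
                e = np.full(len(positions), GAP, dtype=np.int16)
                w = np.zeros(len(positions))
                for j, f in enumerate(fields[1:]):
                    if f == "-":
                        continue
                    allele, wt = f.rsplit(":", 1)
                    e[j] = alleles[j].index(allele)
                    w[j] = float(wt)
                entries.append(e)
                weights.append(w)
        return cls(np.array(entries), np.array(weights), positions, alleles, ids)

    def __repr__(self) -> str:  # pragma: no cover
        return f"AlignmentMatrix(m={self.m}, n={self.n})"
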