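"""Linkage-disequilibrium reference: variant index, pairwise r², per-variant LD scores.

The reference is precomputed or simulated, never derived from genotypes at
run time.  On disk it is a variant index table (snp_id, chrom, pos,
ld_score) plus a sparse pairwise-r² table of (snp_id_a, snp_id_b, r2)
triples; both delimited text, gzip allowed.  r² between pairs absent from
the sparse table is zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class LDReference:
    """Variant positions plus a pairwise-r² accessor and LD scores.

    Invariants: r²(a, a) = 1; r² symmetric in [0, 1]; ld_score ≥ 1
    (a variant is always in full LD with itself).
    """

    def __init__(self, index: pd.DataFrame, pairs: pd.DataFrame | None = None):
        required = {"snp_id", "chrom", "pos", "ld_score"}
        if not required.issubset(index.columns):
            raise ValueError(f"LD index needs columns {sorted(required)}")
        self.index = index.reset_index(drop=True)
        self._pos = dict(zip(self.index.snp_id, self.index.pos))
        self._chrom = dict(zip(self.index.snp_id, self.index.chrom.astype(str)))
        self._ld = dict(zip(self.index.snp_id, self.index.ld_score.astype(float)))
        self._r2: dict[tuple[str, str], float] = {}
        if pairs is not None:
            for a, b, r2 in pairs[["snp_id_a", "snp_id_b", "r2"]].itertuples(index=False):
                key = (a, b) if a <= b else (b, a)
                self._r2[key] = float(r2)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._pos

    @property
    def snp_ids(self) -> list[str]:
        return list(self.index.snp_id)

    def position(self, snp_id: str) -> int:
        return int(self._pos[snp_id])

    def chromosome(self, snp_id: str) -> str:
        return self._chrom[snp_id]

    def ld_score(self, snp_id: str) -> float:
        return self._ld[snp_id]

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a <= b else (b, a)
        return self._r2.get(key, 0.0)

    # ------------------------------------------------------------------ io
    @classmethod
    def from_files(cls, index_path, pairs_path=None) -> "LDReference":
        index = pd.read_csv(index_path, sep=None, engine="python")
        pairs = None
        if pairs_path is not None:
            pairs = pd.read_csv(pairs_path, sep=None, engine="python")
        return cls(index, pairs)

    def to_files(self, index_path, pairs_path) -> None:
        self.index.to_csv(index_path, sep="\t", index=False)
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        pd.DataFrame(rows, columns=["snp_id_a", "snp_id_b", "r2"]).to_csv(
            pairs_path, sep="\t", index=False)

    @classmethod
    def from_blocks(cls, index: pd.DataFrame, block_ids: np.ndarray,
                    r2_within) -> "LDReference":
        """Build from block assignments and a callable r2_within(i, j) giving
        the r² between the i-th and j-th variant of the same block."""
        snps = list(index.snp_id)
        rows = []
        scores = np.ones(len(snps))
        for block in np.unique(block_ids):
            members = np.flatnonzero(block_ids == block)
            for ii, gi in enumerate(members):
                for jj in range(ii + 1, len(members)):
                    gj = members[jj]
                    r2 = float(r2_within(ii, jj))
                    if r2 > 0:
                        rows.append((snps[gi], snps[gj], r2))
                        scores[gi] += r2
                        scores[gj] += r2
        idx = index.copy()
        idx["ld_score"] = scores
        pairs = pd.DataFrame(rows, columns=["snp_id_a", "snp_id_b", "r2"]) \
            if rows else None
        return cls(idx, pairs)
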