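"""Containers for father-mother-offspring trio data.

The unit of analysis throughout the package is the family trio: genotype
dosages (count of the effect allele, 0/1/2) for father ``F``, mother ``M``
and offspring ``O``, together with one quantitative phenotype per member
(``ZF``, ``ZM``, ``ZO``).  Simulated datasets may additionally carry hidden
generative variables (grandparental genotypes, the stratification variable
and confounders) that real data never exposes; analysis code only ever sees
the public six columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PUBLIC_COLUMNS = ("F", "M", "O", "ZF", "ZM", "ZO")
HIDDEN_COLUMNS = ("GF1", "GM1", "GF2", "GM2", "L", "UF", "UM", "UO")


@dataclass
class TrioDataset:
    """Genotypes and phenotypes for a set of family trios at one SNP.

    Parameters
    ----------
    F, M, O
        Genotype dosages in {0, 1, 2} (NaN for missing) for father, mother
        and offspring; equal-length arrays, one entry per trio.
    ZF, ZM, ZO
        Phenotypes of father, mother and offspring.
    covariates
        Optional per-role covariate frames keyed by ``"F"``/``"M"``/``"O"``
        (each a DataFrame with one row per trio), or a single DataFrame
        applied to the offspring.
    hidden
        Optional frame of generative variables kept only for oracle testing
        of the simulator; dropped by :meth:`public_view`.
    family_ids
        Optional identifiers, one per trio.
    """

    F: np.ndarray
    M: np.ndarray
    O: np.ndarray
    ZF: np.ndarray
    ZM: np.ndarray
    ZO: np.ndarray
    covariates: object | None = None
    hidden: pd.DataFrame | None = None
    family_ids: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for name in PUBLIC_COLUMNS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.F)
        for name in PUBLIC_COLUMNS[1:]:
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} has length "
                                 f"{len(getattr(self, name))}, expected {n}")
        if self.hidden is not None and len(self.hidden) != n:
            raise ValueError("hidden frame length does not match trios")

    @property
    def n_trios(self) -> int:
        return len(self.F)

    def mendelian_valid(self) -> np.ndarray:
        """Boolean mask: offspring dosage reachable from the parental pair.

        A parent with dosage 0 transmits 0 copies, with 2 transmits 1, and a
        heterozygote transmits 0 or 1; the reachable set for the child is the
        contiguous range [#homozygous-alt parents, #carrier parents].
        """
        f, m, o = self.F, self.M, self.O
        lo = (f == 2).astype(int) + (m == 2).astype(int)
        hi = (f > 0).astype(int) + (m > 0).astype(int)
        ok = (o >= lo) & (o <= hi)
        return ok | ~np.isfinite(f + m + o)  # missing entries are not judged

    def validate(self) -> "TrioDataset":
        """Raise if any complete trio violates Mendelian transmission."""
        bad = ~self.mendelian_valid()
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"Mendelian inconsistency in trio {idx}: "
                f"F={self.F[idx]}, M={self.M[idx]}, O={self.O[idx]}")
        return self

    def public_view(self) -> "TrioDataset":
        """The analysis view: generative hidden columns removed."""
        return replace(self, hidden=None)

    def complete_cases(self) -> "TrioDataset":
        """Drop trios with any missing public value (listwise deletion)."""
        mask = np.isfinite(self.observed()).all(axis=1)
        if mask.all():
            return self
        return self.take(np.flatnonzero(mask))

    def take(self, idx: np.ndarray) -> "TrioDataset":
        return TrioDataset(
            *(getattr(self, c)[idx] for c in PUBLIC_COLUMNS),
            covariates=_take_covariates(self.covariates, idx),
            hidden=None if self.hidden is None else
            self.hidden.iloc[idx].reset_index(drop=True),
            family_ids=None if self.family_ids is None else
            np.asarray(self.family_ids)[idx],
        )

    def observed(self) -> np.ndarray:
        """The (n, 6) observed matrix in the order (F, M, O, ZF, ZM, ZO)."""
        return np.column_stack([getattr(self, c) for c in PUBLIC_COLUMNS])

    def moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Sample mean (6,) and divisor-``n`` covariance (6, 6)."""
        x = self.observed()
        mean = x.mean(axis=0)
        xc = x - mean
        return mean, xc.T @ xc / len(x)

    def to_frame(self, include_hidden: bool = False) -> pd.DataFrame:
        frame = pd.DataFrame({c: getattr(self, c) for c in PUBLIC_COLUMNS})
        if self.family_ids is not None:
            frame.insert(0, "fid", self.family_ids)
        if include_hidden and self.hidden is not None:
            frame = pd.concat([frame, self.hidden.reset_index(drop=True)],
                              axis=1)
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrioDataset":
        missing = [c for c in PUBLIC_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        hidden_cols = [c for c in HIDDEN_COLUMNS if c in frame.columns]
        return cls(
            *(frame[c].to_numpy(dtype=float) for c in PUBLIC_COLUMNS),
            hidden=frame[hidden_cols].copy() if hidden_cols else None,
            family_ids=frame["fid"].to_numpy() if "fid" in frame.columns
            else None,
        )


def _take_covariates(cov, idx):
    if cov is None:
        return None
    if isinstance(cov, dict):
        return {k: v.iloc[idx].reset_index(drop=True) for k, v in cov.items()}
    return cov.iloc[idx].reset_index(drop=True)
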