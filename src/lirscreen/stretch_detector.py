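"""Detection of confidently predicted interacting stretches.

A stretch is a run of fragment residues that the structure predictor is
confident about in the complex: at least ``min_len`` residues long, mean
pLDDT of at least ``min_plddt`` and mean minPAE of at most ``max_minpae``
(defaults 4 residues / 75 / 8.0 Angstrom; boundary values qualify).

The thresholds apply to interval *averages*, so stretch boundaries are not
uniquely determined by the criteria alone.  The rule used here: an interval
qualifies if it meets all three criteria and contains at least one seed
residue that individually satisfies both score thresholds; the candidate set
is every qualifying interval that is maximal (not contained in a longer
qualifying interval); overlapping candidates are merged into their union when
the union still qualifies, otherwise the one with the higher mean pLDDT is
kept.  The procedure is deterministic and independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Stretch", "DetectionThresholds", "detect_stretches"]


@dataclass(frozen=True)
class DetectionThresholds:
    min_len: int = 4
    min_plddt: float = 75.0
    max_minpae: float = 8.0


DEFAULT_THRESHOLDS = DetectionThresholds()


@dataclass(frozen=True)
class Stretch:
    """A confidently predicted stretch, in fragment-local 1-based coordinates."""

    fragment_id: str
    start: int
    end: int
    mean_plddt: float
    mean_minpae: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def local_range(self) -> range:
        """0-based residue positions within the fragment."""
        return range(self.start - 1, self.end)


def _maximal_qualifying_intervals(
    plddt: np.ndarray,
    minpae: np.ndarray,
    thr: DetectionThresholds,
) -> list[tuple[int, int]]:
    """Maximal qualifying intervals, 0-based inclusive.

    An interval [i, j] qualifies if it is at least ``min_len`` long, its mean
    pLDDT and mean minPAE meet the thresholds, and it contains a seed residue
    individually passing both score cutoffs.  Maximal = not contained in any
    other qualifying interval.  Fully vectorised (L x L masks + prefix sums).
    """
    L = len(plddt)
    seeds = (plddt >= thr.min_plddt) & (minpae <= thr.max_minpae)
    cp = np.concatenate([[0.0], np.cumsum(plddt)])
    cm = np.concatenate([[0.0], np.cumsum(minpae)])
    cs = np.concatenate([[0], np.cumsum(seeds)])
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    n = j - i + 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_p = (cp[j + 1] - cp[i]) / n
        mean_m = (cm[j + 1] - cm[i]) / n
    q = (
        (n >= thr.min_len)
        & (cs[j + 1] - cs[i] > 0)
        & (mean_p >= thr.min_plddt)
        & (mean_m <= thr.max_minpae)
    )
    # supersets of [i, j] live at i' <= i, j' >= j: 2-D prefix sum over that corner
    sup = np.cumsum(np.cumsum(q[:, ::-1], axis=0), axis=1)[:, ::-1]
    ii, jj = np.nonzero(q & (sup == 1))
    return sorted(zip(ii.tolist(), jj.tolist()))


def _mean(arr: np.ndarray, iv: tuple[int, int]) -> float:
    return float(np.mean(arr[iv[0] : iv[1] + 1]))


def _resolve_overlaps(
    intervals: list[tuple[int, int]],
    plddt: np.ndarray,
    minpae: np.ndarray,
    thr: DetectionThresholds,
) -> list[tuple[int, int]]:
    """Merge overlapping candidates into their union when the union still
    qualifies; otherwise keep the higher-mean-pLDDT one (ties: leftmost)."""
    ivs = sorted(set(intervals))
    changed = True
    while changed:
        changed = False
        for a in range(len(ivs) - 1):
            i1, j1 = ivs[a]
            i2, j2 = ivs[a + 1]
            if i2 <= j1:  # sorted by start, so adjacency check suffices
                union = (min(i1, i2), max(j1, j2))
                if (
                    _mean(plddt, union) >= thr.min_plddt
                    and _mean(minpae, union) <= thr.max_minpae
                ):
                    keep = union
                elif _mean(plddt, (i2, j2)) > _mean(plddt, (i1, j1)):
                    keep = (i2, j2)
                else:
                    keep = (i1, j1)
                ivs[a : a + 2] = [keep]
                changed = True
                break
    return ivs


def detect_stretches(
    plddt,
    minpae,
    fragment_id: str = "",
    thresholds: DetectionThresholds = DEFAULT_THRESHOLDS,
) -> list[Stretch]:
    """Find confidently predicted stretches in per-residue score profiles.

    Parameters
    ----------
    plddt, minpae:
        Per-residue profiles over the fragment (same length).
    fragment_id:
        Carried through to the reported stretches.
    thresholds:
        Length and score cutoffs; boundary values are accepted.

    Returns maximal non-overlapping stretches in 1-based fragment coordinates,
    ordered N to C.
    """
    plddt = np.asarray(plddt, dtype=float)
    minpae = np.asarray(minpae, dtype=float)
    if plddt.shape != minpae.shape or plddt.ndim != 1:
        raise ValueError(
            f"profile length mismatch: pLDDT {plddt.shape}, minPAE {minpae.shape}"
        )
    cands = _maximal_qualifying_intervals(plddt, minpae, thresholds)
    final = _resolve_overlaps(cands, plddt, minpae, thresholds)
    return [
        Stretch(
            fragment_id=fragment_id,
            start=i + 1,
            end=j + 1,
            mean_plddt=_mean(plddt, (i, j)),
            mean_minpae=_mean(minpae, (i, j)),
        )
        for (i, j) in final
    ]
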