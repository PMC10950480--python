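"""Residue pairing, optimal superposition and structure-similarity scores.

The module implements the three scores commonly used to compare two
conformations of the same (or closely related) protein, all computed on
the alpha-carbon trace:

* **RMSD** — root-mean-square deviation under the least-squares rigid
  superposition (Kabsch algorithm, closed form via SVD of the 3x3
  cross-covariance, with the reflection corrected so the rotation is
  always proper).
* **GDT** — global distance test: for each distance cutoff c the maximal
  fraction of residue pairs that *some* superposition places within c.
  GDT-TS averages cutoffs 1/2/4/8 Å, GDT-HA 0.5/1/2/4 Å, both reported
  as percentages.
* **TM-score** — length-normalized sum of 1/(1 + (d_i/d0)^2) maximized
  over superpositions, with d0 = 1.24 (L_norm - 15)^(1/3) - 1.8 Å
  (floored at 0.5 Å so short chains keep a positive scale).

GDT and TM both ask for a maximum over superpositions. The search here
is seed-and-refine: least-squares fits seeded on every contiguous
residue window of length 3, 5 and 7 plus the full-length fit, each
refined by refitting on the residues currently inside the cutoff until
the inclusion set is stable (at most 10 rounds). Both the seed and every
refined pose are kept as candidates, so the result is never worse than
the plain full-length fit. This is a deterministic heuristic, not
TM-align's full dynamic-programming search.

Batch alignment is defined to be bitwise identical to the sequential
loop over :func:`align_pair`; parallel or stacked evaluation may never
change a score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, PairingError, TooFewPairsError
from .structure_io import StructureModel

__all__ = [
    "Correspondence",
    "AlignmentResult",
    "pair_residues",
    "kabsch_superpose",
    "rmsd",
    "tm_d0",
    "gdt",
    "gdt_fractions_from_distances",
    "gdt_scores_from_fractions",
    "tm_from_distances",
    "tm_score",
    "align_pair",
    "batch_align",
]

GDT_TS_CUTOFFS = (1.0, 2.0, 4.0, 8.0)
GDT_HA_CUTOFFS = (0.5, 1.0, 2.0, 4.0)
GDT_CUTOFFS = (0.5, 1.0, 2.0, 4.0, 8.0)

ResidueKey = tuple[str, int]  # (chain_id, res_seq)


@dataclass(frozen=True)
class Correspondence:
    """Residue-to-residue mapping between two CA traces.

    ``pairs`` holds (index into reference trace, index into mobile trace),
    strictly increasing on both sides; ``ref_keys``/``mob_keys`` carry the
    (chain_id, res_seq) identity of each paired residue, and
    ``ref_coords``/``mob_coords`` the corresponding L x 3 CA coordinates.
    """

    pairs: tuple[tuple[int, int], ...]
    ref_keys: tuple[ResidueKey, ...]
    mob_keys: tuple[ResidueKey, ...]
    ref_coords: np.ndarray
    mob_coords: np.ndarray

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AlignmentResult:
    """Scores and pose for one reference/mobile pair.

    ``rotation``/``translation`` is the RMSD-optimal (display) transform
    mapping mobile onto reference coordinates; ``per_residue_distance``
    holds the L CA-CA distances under that transform, so
    mean(per_residue_distance**2) == rmsd**2.
    """

    mobile_id: str
    length: int
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    per_residue_distance: np.ndarray
    correspondence: Correspondence
    gdt_fractions: dict[float, float] | None = None
    gdt_ts: float | None = None
    gdt_ha: float | None = None
    tm_score: float | None = None


def _ca_records(model: StructureModel, include_het: bool = False):
    """All-chain CA trace: list of ((chain_id, res_seq), res_name, xyz)."""
    out = []
    for chain, res in model.residues():
        ca = next(
            (
                a
                for a in res.atoms
                if a.name == "CA" and (include_het or not a.is_hetatm)
            ),
            None,
        )
        if ca is not None:
            out.append(((chain.chain_id, res.res_seq), res.res_name, ca.coords))
    return out


def pair_residues(
    ref: StructureModel, mob: StructureModel, mode: str = "strict"
) -> Correspondence:
    """Build the residue correspondence required by all pairwise scores.

    ``strict`` requires equal-length CA traces with identical residue-name
    sequences and pairs positionally; ``by-number`` pairs residues sharing
    (chain_id, res_seq), intersecting the two sets in reference order.
    """
    if mode not in ("strict", "by-number"):
        raise PairingError(f"unknown pairing mode {mode!r}")
    rrec = _ca_records(ref)
    mrec = _ca_records(mob)
    if len(rrec) < 3 or len(mrec) < 3:
        raise TooFewPairsError(
            f"need >= 3 CA residues on both sides, got {len(rrec)} and {len(mrec)}"
        )
    if mode == "strict":
        if len(rrec) != len(mrec):
            raise PairingError(
                f"strict pairing needs equal-length traces: {len(rrec)} vs {len(mrec)}"
            )
        for i, ((rkey, rname, _), (_, mname, _)) in enumerate(zip(rrec, mrec)):
            if rname.upper() != mname.upper():
                raise PairingError(
                    f"residue identity mismatch at position {rkey[1]} "
                    f"(chain {rkey[0]}): {rname} vs {mname}"
                )
        pairs = tuple((i, i) for i in range(len(rrec)))
    else:
        mob_index = {}
        for j, (key, _, _) in enumerate(mrec):
            mob_index.setdefault(key, j)
        pairs_list = []
        last_j = -1
        for i, (key, _, _) in enumerate(rrec):
            j = mob_index.get(key)
            if j is None:
                continue
            if j <= last_j:
                raise PairingError(
                    f"mobile residue order inconsistent with reference at {key}"
                )
            pairs_list.append((i, j))
            last_j = j
        pairs = tuple(pairs_list)
    if len(pairs) < 3:
        raise TooFewPairsError(f"only {len(pairs)} residue pairs; need >= 3")
    return Correspondence(
        pairs=pairs,
        ref_keys=tuple(rrec[i][0] for i, _ in pairs),
        mob_keys=tuple(mrec[j][0] for _, j in pairs),
        ref_coords=np.array([rrec[i][2] for i, _ in pairs], dtype=float),
        mob_coords=np.array([mrec[j][2] for _, j in pairs], dtype=float),
    )


def kabsch_superpose(P: np.ndarray, Q: np.ndarray):
    """Least-squares rigid superposition of Q onto P.

    Returns ``(rotation, translation, rmsd)`` minimizing
    ``|| P - (Q @ rotation.T + translation) ||``; the rotation is always
    proper (determinant +1), with a reflection corrected by flipping the
    singular direction of smallest singular value.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise PairingError(f"point sets must both be L x 3, got {P.shape} vs {Q.shape}")
    L = len(P)
    if L < 3:
        raise TooFewPairsError(f"need >= 3 points, got {L}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - pc, Q - qc
    if min(np.linalg.matrix_rank(Pc, tol=1e-8), np.linalg.matrix_rank(Qc, tol=1e-8)) < 2:
        raise DegenerateGeometryError(
            "point set is collinear; the optimal rotation is not unique"
        )
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = pc - R @ qc
    value = rmsd(P, Q, (R, t))
    return R, t, value


def _apply(Q: np.ndarray, transform) -> np.ndarray:
    if transform is None:
        return Q
    R, t = transform
    return Q @ np.asarray(R, dtype=float).T + np.asarray(t, dtype=float)


def rmsd(P: np.ndarray, Q: np.ndarray, transform=None) -> float:
    """Root-mean-square deviation of transform(Q) from P (identity default)."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise PairingError(f"length mismatch: {P.shape} vs {Q.shape}")
    diff = P - _apply(Q, transform)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def _candidate_transforms(P, Q, include, max_iter=10):
    """Seed-and-refine pose candidates for the max-over-superpositions
    scores. *include* maps a distance array to a boolean inclusion mask."""
    L = len(P)
    seeds = [np.arange(L)]
    for w in (3, 5, 7):
        for s in range(L - w + 1):
            seeds.append(np.arange(s, s + w))
    candidates = []
    for idx in seeds:
        try:
            R, t, _ = kabsch_superpose(P[idx], Q[idx])
        except DegenerateGeometryError:
            continue
        candidates.append((R, t))
        current = idx
        for _ in range(max_iter):
            d = np.linalg.norm(P - _apply(Q, (R, t)), axis=1)
            sub = np.nonzero(include(d))[0]
            if len(sub) < 3 or np.array_equal(sub, current):
                break
            current = sub
            try:
                R, t, _ = kabsch_superpose(P[sub], Q[sub])
            except DegenerateGeometryError:
                break
            candidates.append((R, t))
    return candidates


def gdt_fractions_from_distances(distances, cutoffs) -> dict[float, float]:
    """Fraction of pairs within each cutoff for a *fixed* superposition."""
    d = np.asarray(distances, dtype=float)
    return {float(c): float(np.mean(d <= c)) for c in cutoffs}


def gdt_scores_from_fractions(fractions: dict[float, float]):
    """(GDT-TS, GDT-HA) percentages from per-cutoff fractions."""
    ts = 25.0 * sum(fractions[c] for c in GDT_TS_CUTOFFS)
    ha = 25.0 * sum(fractions[c] for c in GDT_HA_CUTOFFS)
    return ts, ha


def gdt(P, Q, cutoffs=GDT_CUTOFFS):
    """Global distance test between paired coordinate sets.

    Returns ``(fractions, gdt_ts, gdt_ha)`` where ``fractions`` maps each
    cutoff (the requested ones plus the standard 0.5/1/2/4/8 Å set) to
    the maximal under-cutoff fraction found by the seed-and-refine search.
    """
    if not len(tuple(cutoffs)):
        raise PairingError("cutoff list must be non-empty")
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    all_cutoffs = sorted(set(float(c) for c in cutoffs) | set(GDT_CUTOFFS))
    L = len(P)
    fractions: dict[float, float] = {}
    for c in all_cutoffs:
        best = 0.0
        for R, t in _candidate_transforms(P, Q, lambda d, c=c: d <= c):
            d = np.linalg.norm(P - _apply(Q, (R, t)), axis=1)
            best = max(best, float(np.count_nonzero(d <= c)) / L)
        fractions[c] = best
    ts, ha = gdt_scores_from_fractions(fractions)
    return fractions, ts, ha


def tm_d0(L_norm: int, floor: bool = True) -> float:
    """TM-score normalization distance d0 in Å.

    d0 = 1.24 (L_norm - 15)^(1/3) - 1.8; with *floor* (the default) the
    value is clamped to at least 0.5 Å, which keeps d0 positive for
    chains of 21 residues or fewer.
    """
    raw = 1.24 * np.cbrt(L_norm - 15.0) - 1.8
    return float(max(raw, 0.5)) if floor else float(raw)


def tm_from_distances(distances, L_norm: int, d0: float | None = None) -> float:
    """TM functional form for a fixed superposition's distances."""
    d = np.asarray(distances, dtype=float)
    if d0 is None:
        d0 = tm_d0(L_norm)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_norm)


def tm_score(P, Q, L_norm: int | None = None) -> float:
    """Template-modeling score maximized over the seed-and-refine poses.

    ``L_norm`` defaults to the reference length L; refinement refits on
    residues with d < d0 each round.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if L_norm is None:
        L_norm = len(P)
    if L_norm < 3:
        raise PairingError(f"L_norm must be >= 3, got {L_norm}")
    d0 = tm_d0(L_norm)
    best = 0.0
    for R, t in _candidate_transforms(P, Q, lambda d: d < d0):
        d = np.linalg.norm(P - _apply(Q, (R, t)), axis=1)
        best = max(best, tm_from_distances(d, L_norm, d0))
    return best


def align_pair(
    ref: StructureModel,
    mob: StructureModel,
    methods=("rmsd", "gdt", "tm"),
    mode: str = "strict",
) -> AlignmentResult:
    """Pair, superpose and score one reference/mobile structure pair.

    The stored pose is always the RMSD-optimal (least-squares) transform —
    one canonical display pose per pair — and ``per_residue_distance`` is
    measured under it, even when GDT/TM internally search other poses.
    """
    unknown = set(methods) - {"rmsd", "gdt", "tm"}
    if unknown:
        raise PairingError(f"unknown methods: {sorted(unknown)}")
    corr = pair_residues(ref, mob, mode=mode)
    P, Q = corr.ref_coords, corr.mob_coords
    R, t, rmsd_value = kabsch_superpose(P, Q)
    per_res = np.linalg.norm(P - _apply(Q, (R, t)), axis=1)
    result = AlignmentResult(
        mobile_id=mob.model_id,
        length=len(corr),
        rotation=R,
        translation=t,
        rmsd=rmsd_value,
        per_residue_distance=per_res,
        correspondence=corr,
    )
    if "gdt" in methods:
        fractions, ts, ha = gdt(P, Q)
        result.gdt_fractions = fractions
        result.gdt_ts = ts
        result.gdt_ha = ha
    if "tm" in methods:
        result.tm_score = tm_score(P, Q)
    return result


def batch_align(
    ref: StructureModel,
    mobiles,
    methods=("rmsd", "gdt", "tm"),
    mode: str = "strict",
):
    """Align a batch of mobiles against one reference.

    Returns ``(results, errors)``: parallel lists in input order where a
    failed prerequisite leaves ``None`` in *results* and the error message
    in *errors*. Scores are bitwise identical to the sequential loop over
    :func:`align_pair` — a hard contract that any internal parallelism
    must preserve.
    """
    results: list[AlignmentResult | None] = []
    errors: list[str | None] = []
    for mob in mobiles:
        try:
            results.append(align_pair(ref, mob, methods=methods, mode=mode))
            errors.append(None)
        except PairingError as exc:
            results.append(None)
            errors.append(str(exc))
    return results, errors
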