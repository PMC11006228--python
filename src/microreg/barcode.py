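"""Photobleached barcode fiducials.

The barcode is written into the fluorescent gel by a focused laser that
bleaches a set of straight lines; because bleaching extends through the
full depth of the gel, each line is a *vertical plane* in the volume,
described by its in-plane normal azimuth θ and signed offset d:
``cos(θ)·x + sin(θ)·y = d``.

Lines within a family share θ and are spaced by a non-uniform gap code.
Because tissue shrinkage rescales all gaps by a common factor, the
*ratios* of consecutive gaps survive histological processing, and a code
with distinct, non-palindromic gap ratios lets every observed line be
identified regardless of scale or which way the section faces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import permutations, product
from typing import Optional, Sequence

import numpy as np

from .geometry import PlaneMap

__all__ = [
    "BleachPlane",
    "BarcodePattern",
    "ObservedLine",
    "InvalidPatternError",
    "InsufficientFiducialsError",
    "NoCorrespondenceError",
    "design_pattern",
    "default_pattern",
    "predict_section_lines",
    "match_lines",
]


class InvalidPatternError(ValueError):
    """Pattern geometry does not admit unique decoding."""


class InsufficientFiducialsError(ValueError):
    """Too few observed lines to establish correspondence."""


class NoCorrespondenceError(ValueError):
    """No assignment of observed lines to the pattern matches the gap code."""


@dataclass(frozen=True)
class BleachPlane:
    """One vertical bleached plane: n·(x, y) = d with n = (cos θ, sin θ)."""

    theta: float   # radians, in [0, π)
    d: float       # μm, signed offset
    label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta < np.pi:
            raise InvalidPatternError(f"theta must lie in [0, π), got {self.theta}")

    @property
    def normal(self) -> np.ndarray:
        return np.array([np.cos(self.theta), np.sin(self.theta)])


@dataclass(frozen=True)
class BarcodePattern:
    """A set of bleached planes grouped into constant-θ families."""

    planes: tuple[BleachPlane, ...]
    line_width: float   # μm, FWHM of the bleached trough

    def __post_init__(self) -> None:
        labels = [p.label for p in self.planes]
        if len(set(labels)) != len(labels):
            raise InvalidPatternError("plane labels must be unique")
        if self.line_width <= 0:
            raise InvalidPatternError("line_width must be positive")
        object.__setattr__(self, "planes", tuple(self.planes))

    @property
    def families(self) -> dict[float, list[BleachPlane]]:
        """Planes grouped by shared θ, each family sorted by offset."""
        fams: dict[float, list[BleachPlane]] = {}
        for p in self.planes:
            fams.setdefault(p.theta, []).append(p)
        return {t: sorted(ps, key=lambda p: p.d) for t, ps in fams.items()}

    @property
    def single_family(self) -> bool:
        return len(self.families) < 2

    def to_dict(self) -> dict:
        return {
            "planes": [
                {"theta_rad": p.theta, "d_um": p.d, "label": p.label}
                for p in self.planes
            ],
            "line_width_um": self.line_width,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BarcodePattern":
        planes = tuple(
            BleachPlane(p["theta_rad"], p["d_um"], p["label"])
            for p in d["planes"]
        )
        return cls(planes, d["line_width_um"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "BarcodePattern":
        return cls.from_dict(json.loads(s))

    def plane_by_label(self, label: str) -> BleachPlane:
        for p in self.planes:
            if p.label == label:
                return p
        raise KeyError(label)


@dataclass
class ObservedLine:
    """User picks on one dark line in a fluorescence section image."""

    picks: np.ndarray          # (n, 2) of (u, v) μm, n ≥ 2
    label: Optional[str] = None

    def __post_init__(self) -> None:
        picks = np.atleast_2d(np.asarray(self.picks, dtype=float))
        if picks.shape[0] < 2 or picks.shape[1] != 2:
            raise ValueError("an observed line needs at least two (u, v) picks")
        if np.allclose(picks, picks[0], atol=1e-9):
            raise ValueError("picks are all coincident; no line is defined")
        self.picks = picks

    def fit(self) -> tuple[np.ndarray, float]:
        """Total-least-squares line through the picks.

        Returns (normal, rho) with unit normal n and n·(u, v) = rho.
        """
        centroid = self.picks.mean(axis=0)
        _, _, vt = np.linalg.svd(self.picks - centroid)
        direction = vt[0]
        n = np.array([-direction[1], direction[0]])
        return n, float(n @ centroid)

    @property
    def orientation(self) -> float:
        """Line direction angle, radians, in [0, π)."""
        n, _ = self.fit()
        ang = np.arctan2(n[0], -n[1]) % np.pi   # direction = (-n_y, n_x)
        return float(ang)


def _gap_ratio_signature(gaps: np.ndarray) -> np.ndarray:
    return gaps / gaps.sum()


def design_pattern(
    n_per_family: int,
    thetas: Sequence[float],
    base_gap: float,
    gap_code: Sequence[float] | Sequence[Sequence[float]],
    line_width: float,
) -> BarcodePattern:
    """Build a barcode pattern from per-family gap codes.

    Offsets within each family are cumulative sums of
    ``base_gap * gap_code`` starting at 0, so each code must have
    ``n_per_family - 1`` entries.  ``gap_code`` may be one code shared
    by all families or one code per family.  Each normalized gap
    sequence must not equal its own reversal (a flipped section would
    decode ambiguously), and no two families may share a code up to
    reversal: when the section is nearly vertical every bleached plane
    projects to a near-vertical trace, families cannot be told apart by
    orientation, and identical codes would admit a mirror-image plane
    solution that fits the picks exactly.
    """
    codes = np.asarray(gap_code, dtype=float)
    if codes.ndim == 1:
        codes = np.tile(codes, (len(thetas), 1))
        if len(thetas) > 1:
            raise InvalidPatternError(
                "a single shared gap code is ambiguous across families; "
                "give one distinct code per family")
    if codes.shape != (len(thetas), n_per_family - 1):
        raise InvalidPatternError(
            f"need {len(thetas)} codes of {n_per_family - 1} entries each")
    if np.any(codes <= 0):
        raise InvalidPatternError("gap ratios must be positive")
    sigs = []
    for code in codes:
        sig = _gap_ratio_signature(code)
        if len(code) >= 2 and np.allclose(sig, sig[::-1], rtol=1e-9):
            raise InvalidPatternError(
                "gap code is palindromic: ambiguous under section reflection")
        sigs.append(sig)
    for i in range(len(sigs)):
        for j in range(i + 1, len(sigs)):
            if (np.allclose(sigs[i], sigs[j], rtol=1e-9)
                    or np.allclose(sigs[i], sigs[j][::-1], rtol=1e-9)):
                raise InvalidPatternError(
                    "two families share a gap code (up to reversal); "
                    "family identity would be ambiguous")

    planes: list[BleachPlane] = []
    for fam_idx, (theta, code) in enumerate(zip(thetas, codes)):
        offsets = np.concatenate([[0.0], np.cumsum(base_gap * code)])
        fam_name = chr(ord("A") + fam_idx)
        for line_idx, d in enumerate(offsets):
            planes.append(BleachPlane(float(theta) % np.pi, float(d),
                                      f"{fam_name}{line_idx}"))
    return BarcodePattern(tuple(planes), float(line_width))


def default_pattern() -> BarcodePattern:
    """Two perpendicular families of 4 lines, base gap 200 μm, line
    width 25 μm.

    Codes [1, 1.25, 3.5] and [1, 3.75, 2], chosen by exhaustive search
    so that every contiguous gap window of length ≥ 2 of either family,
    forward or reversed, differs from every other such window by at
    least 24% in shape — comfortably above the 15% matching tolerance —
    while keeping the smallest gap at the full base gap (so pick noise
    stays a small fraction of any gap).  Partially visible families
    then still decode unambiguously, and no window of a family matches
    a shifted or reversed window of the same family.
    """
    return design_pattern(4, [0.0, np.pi / 2], 200.0,
                          [[1.0, 1.25, 3.5], [1.0, 3.75, 2.0]], 25.0)


def _clip_segment(
    a: float, b: float, c: float, extent: tuple[float, float]
) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Clip line a·u + b·v + c = 0 to [0, W] × [0, H]; None if outside."""
    w, h = extent
    pts = []
    # Intersections with the four rectangle edges.
    if abs(b) > 1e-15:
        for u in (0.0, w):
            v = -(a * u + c) / b
            if -1e-9 <= v <= h + 1e-9:
                pts.append((u, min(max(v, 0.0), h)))
    if abs(a) > 1e-15:
        for v in (0.0, h):
            u = -(b * v + c) / a
            if -1e-9 <= u <= w + 1e-9:
                pts.append((min(max(u, 0.0), w), v))
    if len(pts) < 2:
        return None
    pts = np.asarray(pts)
    # Pick the two most distant intersection points (corners may duplicate).
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    if d2[i, j] < 1e-12:
        return None
    return pts[i], pts[j]


def predict_section_lines(
    pattern: BarcodePattern,
    m: PlaneMap,
    extent: tuple[float, float],
) -> list[tuple[str, tuple[float, float, float], tuple[np.ndarray, np.ndarray]]]:
    """Predict where each bleached plane intersects the section.

    For bleach plane k the section-plane line is
    ``n_k · (linear₂ · (u, v) + offset₂) = d_k`` where linear₂/offset₂
    are the x, y rows of the map.  Returns ``(label, (a, b, c), (p0, p1))``
    per visible plane with a·u + b·v + c = 0 and the segment clipped to
    the extent; planes missing the extent are omitted.
    """
    m.require_nondegenerate()
    linear2 = m.linear[:2, :]
    offset2 = m.offset[:2]
    out = []
    for p in pattern.planes:
        n = p.normal
        ab = n @ linear2
        c = float(n @ offset2 - p.d)
        norm = np.linalg.norm(ab)
        if norm < 1e-12:
            continue   # bleach plane parallel to the section: no line
        a, b = ab / norm
        c /= norm
        seg = _clip_segment(a, b, c, extent)
        if seg is None:
            continue
        out.append((p.label, (float(a), float(b), float(c)), seg))
    return out


def _cluster_by_orientation(
    lines: Sequence[ObservedLine], tol_deg: float
) -> list[list[int]]:
    """Single-linkage clustering of line indices by orientation mod π.

    Orientations are sorted on the half-circle and split wherever the
    circular gap between neighbors exceeds the tolerance, so a family
    of noisy near-parallel lines stays one cluster regardless of which
    line is visited first.
    """
    tol = np.deg2rad(tol_deg)
    angles = np.array([l.orientation for l in lines])
    order = np.argsort(angles)
    sorted_angles = angles[order]
    n = len(lines)
    if n == 1:
        return [[0]]
    gaps = np.diff(sorted_angles)
    wrap_gap = np.pi - (sorted_angles[-1] - sorted_angles[0])
    breaks = np.nonzero(gaps > tol)[0]
    if len(breaks) == 0:
        return [list(order)]
    # Chain is circular: if the wrap-around gap is small, the first and
    # last runs belong together.
    runs: list[list[int]] = []
    start = 0
    for b in breaks:
        runs.append([int(order[i]) for i in range(start, b + 1)])
        start = b + 1
    runs.append([int(order[i]) for i in range(start, n)])
    if wrap_gap <= tol and len(runs) > 1:
        runs[0] = runs.pop() + runs[0]
    return runs


def _match_gaps(
    observed_gaps: np.ndarray, family_gaps: np.ndarray, tol: float
) -> Optional[tuple[float, int, bool]]:
    """Match observed gaps to a contiguous window of family gaps.

    Tries forward and reversed windows with a free global scale.
    Returns (score, start index in the family, reversed?) of the best
    match within tolerance, else None.
    """
    p = len(observed_gaps)
    if p == 0 or p > len(family_gaps):
        return None
    best: Optional[tuple[float, int, bool]] = None
    for rev in (False, True):
        fg = family_gaps[::-1] if rev else family_gaps
        for start in range(len(fg) - p + 1):
            window = fg[start:start + p]
            scale = observed_gaps.sum() / window.sum()
            rel = np.abs(observed_gaps - scale * window) / (scale * window)
            score = float(rel.max())
            if score <= tol and (best is None or score < best[0]):
                best = (score, start, rev)
    return best


def _inplane_fit_rms(
    observed: Sequence[ObservedLine],
    labels: dict[int, str],
    pattern: BarcodePattern,
) -> Optional[float]:
    """RMS residual (μm) of the 6-unknown in-plane least squares under a
    candidate label assignment; None when the geometry is rank deficient.

    Used as the geometric-consistency score when gap-ratio decoding
    alone is ambiguous (e.g. both families share a gap code and all
    traces are near-vertical).
    """
    rows, rhs = [], []
    for idx, label in labels.items():
        plane = pattern.plane_by_label(label)
        nx, ny = plane.normal
        for u, v in observed[idx].picks:
            rows.append([nx * u, nx * v, nx, ny * u, ny * v, ny])
            rhs.append(plane.d)
    if len(rows) < 7:
        # with 6 unknowns, at least one redundant equation is needed for
        # the residual to discriminate anything
        return None
    a = np.asarray(rows)
    b = np.asarray(rhs)
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 6:
        return None
    resid = a @ sol - b
    return float(np.sqrt(np.mean(resid ** 2)))


def match_lines(
    observed: Sequence[ObservedLine],
    pattern: BarcodePattern,
    orientation_tol_deg: float = 10.0,
    gap_tol: float = 0.15,
) -> tuple[dict[int, str], float]:
    """Assign pattern labels to observed lines by gap-ratio decoding.

    Observed lines are first clustered by trace orientation.  When the
    clusters separate (sections cut at a large tilt, so the two plane
    families project at visibly different angles), each cluster is
    ordered by position along its common normal and its consecutive-gap
    sequence is matched — with a free global scale, forward or reversed
    — against each family's gap code, assigning clusters to distinct
    families with minimal total score.

    In the histologically typical geometry the section is itself nearly
    vertical, every vertical bleach plane projects to a nearly vertical
    trace, and all observed lines fall into *one* orientation cluster
    with the two families interleaved by position.  In that case the
    decoder searches over all ways of splitting the position-ordered
    lines between the families, keeps the splits whose per-family gap
    sequences match the codes, and picks the split with the smallest
    in-plane least-squares residual (each vertical plane family
    constrains a different combination of the in-plane unknowns, so a
    swapped or shifted assignment fits the picks measurably worse).

    Returns ``(correspondence, score)`` where correspondence maps the
    index in ``observed`` to a plane label and score is the worst
    relative gap deviation over matched clusters (0 for a perfect
    match).
    """
    if len(observed) < 3:
        raise InsufficientFiducialsError(
            f"need at least 3 observed lines, got {len(observed)}")

    clusters = _cluster_by_orientation(observed, orientation_tol_deg)
    if len(clusters) == 1 and not pattern.single_family:
        return _match_interleaved(observed, pattern, gap_tol)

    # Order lines within each cluster by signed position along the
    # cluster's mean normal direction.
    ordered_clusters: list[tuple[list[int], np.ndarray]] = []
    for members in clusters:
        normals, rhos = [], []
        ref_n: Optional[np.ndarray] = None
        for idx in members:
            n, rho = observed[idx].fit()
            if ref_n is None:
                ref_n = n
            elif n @ ref_n < 0:
                n, rho = -n, -rho
            normals.append(n)
            rhos.append(rho)
        order = np.argsort(rhos)
        members_sorted = [members[i] for i in order]
        positions = np.asarray(rhos)[order]
        ordered_clusters.append((members_sorted, positions))

    families = pattern.families
    fam_keys = list(families)
    fam_gaps = {
        t: np.diff([p.d for p in families[t]]) for t in fam_keys
    }

    # Try all injective assignments of clusters to families; usually 2x2.
    best_total: Optional[float] = None
    best_assign: Optional[dict[int, str]] = None
    n_fam = len(fam_keys)
    n_cl = len(ordered_clusters)
    if n_cl > n_fam:
        raise NoCorrespondenceError(
            f"{n_cl} orientation clusters but only {n_fam} pattern families")
    for perm in permutations(fam_keys, n_cl):
        total = 0.0
        assign: dict[int, str] = {}
        ok = True
        for (members, positions), theta in zip(ordered_clusters, perm):
            fam_planes = families[theta]
            if len(members) < 2 or len(members) > len(fam_planes):
                ok = False
                break
            gaps = np.diff(positions)
            hit = _match_gaps(gaps, fam_gaps[theta], gap_tol)
            if hit is None:
                ok = False
                break
            score, start, rev = hit
            total = max(total, score)
            labels = [p.label for p in fam_planes]
            if rev:
                labels = labels[::-1]
            for k, idx in enumerate(members):
                assign[idx] = labels[start + k]
        if ok and (best_total is None or total < best_total):
            best_total = total
            best_assign = assign
    if best_assign is None:
        raise NoCorrespondenceError(
            "no family/order assignment matches the gap code within tolerance")
    return best_assign, float(best_total)


def _match_interleaved(
    observed: Sequence[ObservedLine],
    pattern: BarcodePattern,
    gap_tol: float,
) -> tuple[dict[int, str], float]:
    """Decode a single orientation cluster with interleaved families.

    All observed lines share (nearly) one trace orientation; order them
    by position and search over assignments of each line to a family.
    A candidate assignment is feasible when every family's positional
    gap sequence matches a contiguous window of its gap code (free
    scale, either direction) and every family retains at least two
    lines.  Feasible candidates are ranked by the in-plane fit residual.
    """
    # Positions along a single shared normal.  Projecting every line's
    # centroid onto the *mean* trace normal suppresses each line's own
    # orientation noise (with two picks per line it is the dominant
    # error in a per-line n·centroid position).
    angles = np.array([line.orientation for line in observed])
    mean_dir = 0.5 * np.arctan2(np.sin(2 * angles).sum(),
                                np.cos(2 * angles).sum())
    n_bar = np.array([np.sin(mean_dir), -np.cos(mean_dir)])
    rhos = [float(n_bar @ line.picks.mean(axis=0)) for line in observed]
    order = np.argsort(rhos)
    positions = np.asarray(rhos)[order]
    angles = angles[order]

    def fam_angle_spread(ranks: list[int]) -> float:
        a = angles[ranks]
        d = np.abs(a[:, None] - a[None, :])
        d = np.minimum(d, np.pi - d)
        return float(d.max())

    families = pattern.families
    fam_keys = list(families)
    fam_gaps = {t: np.diff([p.d for p in families[t]]) for t in fam_keys}

    n_obs = len(observed)
    # (rms, spread, score) → assignment; ranked lexicographically
    best_key: Optional[tuple[float, float, float]] = None
    best_assign: Optional[dict[int, str]] = None
    for combo in product(range(len(fam_keys)), repeat=n_obs):
        members: dict[int, list[int]] = {}
        for pos_rank, fam_idx in enumerate(combo):
            members.setdefault(fam_idx, []).append(pos_rank)
        if len(members) < min(2, len(fam_keys)):
            continue
        # A family seen through only two lines spans a single gap, which
        # matches any code window under the free scale; require three.
        if any(len(v) < 3 for v in members.values()):
            continue
        assign: dict[int, str] = {}
        score = 0.0
        spread = 0.0
        ok = True
        for fam_idx, ranks in members.items():
            theta = fam_keys[fam_idx]
            fam_planes = families[theta]
            if len(ranks) > len(fam_planes):
                ok = False
                break
            gaps = np.diff(positions[ranks])
            hit = _match_gaps(gaps, fam_gaps[theta], gap_tol)
            if hit is None:
                ok = False
                break
            sc, start, rev = hit
            score = max(score, sc)
            spread = max(spread, fam_angle_spread(ranks))
            labels = [p.label for p in fam_planes]
            if rev:
                labels = labels[::-1]
            for k, pos_rank in enumerate(ranks):
                assign[int(order[pos_rank])] = labels[start + k]
        if not ok:
            continue
        rms = _inplane_fit_rms(observed, assign, pattern)
        if rms is None:
            rms = float("inf")
        # Rank by pick-fit residual (the most direct evidence), then
        # within-family orientation spread, then gap agreement.
        key = (rms, spread, score)
        if best_key is None or key < best_key:
            best_key = key
            best_assign = assign
    if best_assign is None:
        raise NoCorrespondenceError(
            "no interleaved family assignment matches the gap codes "
            "within tolerance")
    return best_assign, float(best_key[2])
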