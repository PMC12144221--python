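"""Shared fixtures: small study designs and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from phantomqa.design import Geometry, LesionSpec, StudyDesign, TubeSetting


@pytest.fixture
def small_geometry() -> Geometry:
    return Geometry(n_slices=4, n_rows=64, n_cols=64,
                    pixel_size_mm=0.41, slice_thickness_mm=0.75)


@pytest.fixture
def small_design(small_geometry) -> StudyDesign:
    doses = (1.0, 2.0, 4.0, 8.0)
    tube = {d: TubeSetting(120, int(15 * d), 0.5) for d in doses}
    return StudyDesign(doses_mGy=doses, reconstructions=("IR", "FBP"),
                       repetitions=3, geometry=small_geometry, tube=tube)


@pytest.fixture
def small_lesions(small_geometry) -> list[LesionSpec]:
    return [
        LesionSpec("MCA", (1, 20.0, 16.0), 4.0),
        LesionSpec("ACoA", (2, 44.0, 44.0), 4.0),
        LesionSpec("BA", (3, 16.0, 48.0), 2.0),
    ]


# ---------------------------------------------------------------------------
# independent oracles (pure-python, loop-based; never reuse package code)
# ---------------------------------------------------------------------------

def mask_oracle(pixels: np.ndarray, threshold: int) -> np.ndarray:
    """Per-pixel loop over every voxel: blue <= threshold."""
    S, R, C, _ = pixels.shape
    out = np.zeros((S, R, C), dtype=bool)
    for s in range(S):
        for r in range(R):
            for c in range(C):
                out[s, r, c] = pixels[s, r, c, 2] <= threshold
    return out


def flood_fill_oracle(mask: np.ndarray) -> list[frozenset]:
    """Connected components by BFS flood fill with 26-neighborhood."""
    S, R, C = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    offsets = [
        (ds, dr, dc)
        for ds in (-1, 0, 1) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
        if (ds, dr, dc) != (0, 0, 0)
    ]
    for s in range(S):
        for r in range(R):
            for c in range(C):
                if not mask[s, r, c] or seen[s, r, c]:
                    continue
                stack, comp = [(s, r, c)], set()
                seen[s, r, c] = True
                while stack:
                    cur = stack.pop()
                    comp.add(cur)
                    for ds, dr, dc in offsets:
                        ns, nr, nc = cur[0] + ds, cur[1] + dr, cur[2] + dc
                        if (0 <= ns < S and 0 <= nr < R and 0 <= nc < C
                                and mask[ns, nr, nc] and not seen[ns, nr, nc]):
                            seen[ns, nr, nc] = True
                            stack.append((ns, nr, nc))
                comps.append(frozenset(comp))
    return comps


def intensity_oracle(pixels: np.ndarray, coords) -> float:
    """Loop-based mean of inverted normalized BT.601 gray."""
    total = 0.0
    for s, r, c in coords:
        rgb = pixels[s, r, c]
        gray = 0.299 * rgb[0] + 0.587 * rgb[1] + 0.114 * rgb[2]
        total += (255.0 - gray) / 255.0
    return total / len(coords)


def assignment_oracle(lesion_pos, comp_pos, tolerance):
    """Minimum-total-distance one-to-one assignment by exhaustive
    enumeration over all injections of lesions into components (pairs
    beyond tolerance forbidden). Returns {lesion index: comp index}."""
    import itertools

    nl, nc = len(lesion_pos), len(comp_pos)
    best, best_cost, best_size = {}, np.inf, -1
    comp_indices = list(range(nc))
    for k in range(min(nl, nc), -1, -1):
        for lesion_subset in itertools.combinations(range(nl), k):
            for comp_perm in itertools.permutations(comp_indices, k):
                cost = 0.0
                ok = True
                for li, ci in zip(lesion_subset, comp_perm):
                    d = float(np.linalg.norm(
                        np.asarray(lesion_pos[li]) - np.asarray(comp_pos[ci])
                    ))
                    if d > tolerance:
                        ok = False
                        break
                    cost += d
                if ok and (k > best_size or (k == best_size and cost < best_cost)):
                    best = dict(zip(lesion_subset, comp_perm))
                    best_cost, best_size = cost, k
        if best_size == k and best_size >= 0:
            # maximum-cardinality matchings found at this k; stop
            break
    return best


def mwu_exact_oracle(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all C(n, n_x)
    labelings of the pooled sample (assumes no ties)."""
    import itertools
    from math import comb

    x, y = list(x), list(y)
    pooled = x + y
    n_x, n = len(x), len(pooled)

    def u_of(sample_x, sample_y):
        return sum(1 for a in sample_x for b in sample_y if a > b)

    u_obs = u_of(x, y)
    mean_u = n_x * (n - n_x) / 2.0
    count_le = count_ge = total = 0
    for idx in itertools.combinations(range(n), n_x):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in idx]
        u = u_of(xs, ys)
        total += 1
        if u <= u_obs:
            count_le += 1
        if u >= u_obs:
            count_ge += 1
    p = min(1.0, 2.0 * min(count_le, count_ge) / total)
    return float(u_obs), p
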