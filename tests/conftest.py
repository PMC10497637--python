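import numpy as np
import pytest

from coralcarb import synthetic as syn


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noiseless sinusoidal phantom with its ground truth (session-shared)."""
    params = syn.RadiographPhantomParams(noise_sd=0.0)
    return syn.generate_radiograph(params, seed=123)


@pytest.fixture(scope="session")
def solid_phantom_with_pores():
    """Solid-aragonite matrix with 20% planted pores, 1 gray level of noise."""
    params = syn.RadiographPhantomParams(
        band_profile=lambda x: np.full_like(np.asarray(x, dtype=float), 2.83),
        pore_fraction=0.20,
        noise_sd=1.0,
    )
    return syn.generate_radiograph(params, seed=77)


def flood_fill_components(mask: np.ndarray, connectivity: int = 8):
    """Brute-force BFS flood fill; independent oracle for particle counting.

    Returns sorted (descending) component pixel areas."""
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    areas = []
    rows, cols = mask.shape
    for r0, c0 in zip(*np.nonzero(mask)):
        if visited[r0, c0]:
            continue
        stack = [(r0, c0)]
        visited[r0, c0] = True
        area = 0
        while stack:
            r, c = stack.pop()
            area += 1
            for dr, dc in nbrs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc] and not visited[rr, cc]:
                    visited[rr, cc] = True
                    stack.append((rr, cc))
        areas.append(area)
    return sorted(areas, reverse=True)
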