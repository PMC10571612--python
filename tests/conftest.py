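import numpy as np
import pytest

import pchsim as ps


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_params():
    return ps.SimulationParameters()


def dense_ball(radius: float, spacing: float = 0.9, centre=(0.0, 0.0, 0.0)):
    """Cubic-lattice ball of points — a constructed condensate stand-in."""
    g = np.arange(-radius, radius + spacing / 2, spacing)
    pts = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = pts[np.linalg.norm(pts, axis=1) <= radius]
    return pts + np.asarray(centre)


def dense_shell(r_in: float, r_out: float, spacing: float = 0.9,
                centre=(0.0, 0.0, 0.0)):
    g = np.arange(-r_out, r_out + spacing / 2, spacing)
    pts = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
    r = np.linalg.norm(pts, axis=1)
    return pts[(r >= r_in) & (r <= r_out)] + np.asarray(centre)


def _rsa_region(accept, bound: float, min_dist: float, seed: int,
                max_trials: int = 60_000):
    """Random sequential adsorption: liquid-like packing inside a region."""
    rng = np.random.default_rng(seed)
    pts = []
    grid = {}
    cell = min_dist
    md2 = min_dist * min_dist
    cand = rng.uniform(-bound, bound, (max_trials, 3))
    for p in cand:
        if not accept(p):
            continue
        key = tuple((p // cell).astype(int))
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for q in grid.get((key[0] + dx, key[1] + dy, key[2] + dz), ()):
                        d = p - q
                        if d @ d < md2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts.append(p)
            grid.setdefault(key, []).append(p)
    return np.asarray(pts)


def packed_ball(radius: float, min_dist: float = 1.0, seed: int = 0,
                centre=(0.0, 0.0, 0.0)):
    """Liquid-density ball of points (RSA packing), like an LJ condensate."""
    pts = _rsa_region(lambda p: p @ p <= radius * radius, radius, min_dist, seed)
    return pts + np.asarray(centre)


def packed_shell(r_in: float, r_out: float, min_dist: float = 1.0,
                 seed: int = 0, centre=(0.0, 0.0, 0.0)):
    def accept(p):
        r2 = p @ p
        return r_in * r_in <= r2 <= r_out * r_out

    return _rsa_region(accept, r_out, min_dist, seed) + np.asarray(centre)
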