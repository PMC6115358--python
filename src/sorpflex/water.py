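"""Rigid 3-site water (SPC/E) construction and insertion geometry."""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from .forcefield import ForceField, load_forcefield
from .model import InvalidInputError


@lru_cache(maxsize=None)
def spce() -> ForceField:
    return load_forcefield("spce")


def reference_geometry(ff: ForceField = None) -> np.ndarray:
    """(3,3) body-frame coordinates [O, H1, H2] from the parameter file.

    The oxygen sits at the body origin; the dipole points along +z.
    """
    ff = ff or spce()
    r_oh = ff.extra["rigid"]["r_oh"]
    theta = math.radians(ff.extra["rigid"]["theta_hoh_deg"])
    h = theta / 2.0
    return np.array([
        [0.0, 0.0, 0.0],
        [r_oh * math.sin(h), 0.0, r_oh * math.cos(h)],
        [-r_oh * math.sin(h), 0.0, r_oh * math.cos(h)],
    ])


def quaternion_to_matrix(q) -> np.ndarray:
    q = np.asarray(q, dtype=float).reshape(4)
    n = np.linalg.norm(q)
    if not np.isfinite(n) or abs(n - 1.0) > 1e-8:
        raise InvalidInputError("orientation quaternion must be normalized")
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def random_quaternion(rng) -> np.ndarray:
    """Uniform random rotation (Shoemake's method)."""
    u1, u2, u3 = rng.random(3)
    return np.array([
        math.sqrt(1 - u1) * math.sin(2 * math.pi * u2),
        math.sqrt(1 - u1) * math.cos(2 * math.pi * u2),
        math.sqrt(u1) * math.sin(2 * math.pi * u3),
        math.sqrt(u1) * math.cos(2 * math.pi * u3),
    ])


def water_site_params(ff: ForceField = None):
    """Per-site (species, charge, sigma, epsilon, mass, donor_h, acceptor)
    arrays in [O, H1, H2] order."""
    ff = ff or spce()
    o = ff.atoms["OW"]
    h = ff.atoms["HW"]
    species = np.array(["OW", "HW", "HW"], dtype=object)
    charge = np.array([o.charge, h.charge, h.charge])
    sigma = np.array([o.sigma, h.sigma, h.sigma])
    epsilon = np.array([o.epsilon, h.epsilon, h.epsilon])
    mass = np.array([o.mass, h.mass, h.mass])
    donor_h = np.array([False, True, True])
    acceptor = np.array([True, False, False])
    return species, charge, sigma, epsilon, mass, donor_h, acceptor


def make_water(position, orientation, ff: ForceField = None):
    """Build one rigid SPC/E water.

    Parameters
    ----------
    position : (3,) nm, oxygen position.
    orientation : unit quaternion (w, x, y, z).

    Returns
    -------
    positions : (3, 3) site coordinates [O, H1, H2]
    params : tuple of per-site parameter arrays (see
        :func:`water_site_params`)
    """
    ff = ff or spce()
    R = quaternion_to_matrix(orientation)
    body = reference_geometry(ff)
    pos = np.asarray(position, dtype=float).reshape(3)
    coords = pos[None, :] + body @ R.T
    return coords, water_site_params(ff)


def water_dipole(coords3) -> np.ndarray:
    """Unit dipole direction of a water given its [O, H1, H2] coordinates."""
    d = 0.5 * (coords3[1] + coords3[2]) - coords3[0]
    return d / np.linalg.norm(d)
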