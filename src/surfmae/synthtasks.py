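"""Synthetic desk-scale datasets for the three downstream tasks.

These emulate the *shape* of the real benchmarks — per-point binary site
labels, 7-way pocket classes, paired interacting surfaces — with labels that
are functions of the generated geometry/chemistry, so that learnability can
be verified end-to-end without external data.
"""

from __future__ import annotations

import numpy as np

from .config import ELEMENTS, SurfaceConfig
from .ingest import AtomCloud, center_atoms, one_hot, synth_chain
from .surface import SurfaceCloud, SurfaceRejection, build_surface


def _build(chain: AtomCloud, cfg: SurfaceConfig, seed: int) -> SurfaceCloud:
    cloud = build_surface(chain, cfg, seed)
    if isinstance(cloud, SurfaceRejection):
        raise RuntimeError(f"synthetic chain unexpectedly rejected: {cloud}")
    return cloud


def make_site_dataset(
    n_chains: int, cfg: SurfaceConfig, seed: int, n_residues: int = 24
) -> list[tuple[SurfaceCloud, np.ndarray]]:
    """Per-point binary labels: 1 iff the mean curvature at the second scale
    exceeds its per-protein median (a purely geometric 'interface')."""
    out = []
    ss = np.random.SeedSequence([seed, 11])
    for child in ss.spawn(n_chains):
        s = int(child.generate_state(1)[0] % (2**31))
        chain = synth_chain(n_residues, seed=s)
        cloud = _build(chain, cfg, seed=s)
        h2 = cloud.curvatures[:, 2]  # H at the second scale
        labels = (h2 > np.median(h2)).astype(int)
        out.append((cloud, labels))
    return out


#: per-class (p_S, p_Se, p_O) side-chain signatures — distinct points in
#: composition space so each surrogate "cofactor class" has its own chemical
#: fingerprint, the way real cofactor pockets differ in residue makeup
_POCKET_SIGNATURES = [
    (0.01, 0.01, 0.30),
    (0.14, 0.01, 0.22),
    (0.01, 0.12, 0.22),
    (0.28, 0.02, 0.12),
    (0.02, 0.24, 0.12),
    (0.36, 0.08, 0.05),
    (0.18, 0.18, 0.05),
]


def synth_pocket_chain(class_id: int, seed: int, base_residues: int = 12) -> AtomCloud:
    """Protein-like chain whose generative class controls both size and
    side-chain element composition (a class-specific sulfur/selenium/oxygen
    signature), giving geometric and chemical class signal."""
    if not 0 <= class_id < 7:
        raise ValueError("class_id must be in 0..6")
    rng = np.random.default_rng(np.random.SeedSequence([seed, class_id, 23]))
    n_res = base_residues + 3 * class_id
    base = synth_chain(n_res, seed=int(rng.integers(2**31)))
    p_s, p_se, p_o = _POCKET_SIGNATURES[class_id]
    probs = np.array([1.0 - p_s - p_se - p_o - 0.15, 0.0, p_o, 0.15, p_s, p_se])
    types = base.types.copy()
    for i in range(base.n_atoms):
        if rng.random() < 0.9:  # leave some atoms untouched
            types[i] = one_hot(ELEMENTS[rng.choice(6, p=probs)])
    return AtomCloud(base.coords, types, chain_id=f"POCKET{class_id}",
                     source=f"synth_pocket(class={class_id}, seed={seed})")


def make_pocket_dataset(
    n_per_class: int, cfg: SurfaceConfig, seed: int
) -> list[tuple[SurfaceCloud, int]]:
    """Balanced 7-class dataset of synthetic pocket surfaces."""
    out = []
    for c in range(7):
        for i in range(n_per_class):
            s = int(np.random.SeedSequence([seed, c, i, 31]).generate_state(1)[0]
                    % (2**31))
            chain = synth_pocket_chain(c, seed=s)
            out.append((_build(chain, cfg, seed=s), c))
    return out


def make_ppi_pair(
    cfg: SurfaceConfig, seed: int, n_residues: int = 20, contact_cutoff: float = 1.0
) -> tuple[SurfaceCloud, SurfaceCloud, np.ndarray]:
    """A synthetic interacting pair: a chain and its mirror image placed in
    surface contact across a plane, which makes the two surfaces locally
    complementary at the interface.

    Positive pairs are cross-surface point pairs within ``contact_cutoff`` Å
    in the complex frame; each returned cloud is centered in its own frame.
    """
    chain_a0 = synth_chain(n_residues, seed=seed)
    x_plane = chain_a0.coords[:, 0].max() + 1.0
    # interacting surfaces carry an intrinsic chemical signature (as real
    # interfaces do): atoms near the contact plane are sulfur-enriched, so a
    # descriptor can learn interface chemistry rather than memorising where
    # a particular chain touched its partner
    rng = np.random.default_rng(np.random.SeedSequence([seed, 53]))
    types = chain_a0.types.copy()
    near = chain_a0.coords[:, 0] > x_plane - 4.0
    for i in np.flatnonzero(near):
        if rng.random() < 0.85:
            types[i] = one_hot("S")
    chain_a = AtomCloud(chain_a0.coords, types, chain_id="A",
                        source=chain_a0.source + "|iface")
    cloud_a = _build(chain_a, cfg, seed=seed)
    # mirror through a plane slightly inside the rightmost surface region, so
    # the two surfaces share an extended (not single-point) contact patch;
    # deepen the overlap until the subsampled surfaces actually register
    # contacts at the configured cutoff
    for shift in (0.75, 1.25, 1.75, 2.5):
        x_plane = cloud_a.points[:, 0].max() - shift
        coords_b = chain_a.coords.copy()
        coords_b[:, 0] = 2 * x_plane - coords_b[:, 0]
        chain_b_complex = AtomCloud(coords_b, chain_a.types, chain_id="B",
                                    source=chain_a.source + "|mirror")
        cloud_b_complex = _build(chain_b_complex, cfg, seed=seed + 1)
        d = np.linalg.norm(
            cloud_a.points[:, None, :] - cloud_b_complex.points[None, :, :], axis=2
        )
        pos = np.argwhere(d < contact_cutoff)
        if len(pos) >= 3:
            break
    if len(pos) == 0:
        raise RuntimeError("mirrored pair produced no contact pairs")

    # recenter B in its own frame (points and atoms shift identically, so
    # curvature and chemical features are unaffected)
    shift = cloud_b_complex.points.mean(axis=0)
    cloud_b = SurfaceCloud(
        points=cloud_b_complex.points - shift,
        normals=cloud_b_complex.normals,
        curvatures=cloud_b_complex.curvatures,
        chem_raw=cloud_b_complex.chem_raw,
        chem_neighbor_idx=cloud_b_complex.chem_neighbor_idx,
        atoms=center_atoms(chain_b_complex),
        seed=cloud_b_complex.seed,
    )
    return cloud_a, cloud_b, pos


def make_ppi_dataset(
    n_pairs: int, cfg: SurfaceConfig, seed: int, n_residues: int = 20
) -> list[tuple[SurfaceCloud, SurfaceCloud, np.ndarray]]:
    out = []
    for i in range(n_pairs):
        s = int(np.random.SeedSequence([seed, i, 41]).generate_state(1)[0] % (2**31))
        out.append(make_ppi_pair(cfg, seed=s, n_residues=n_residues))
    return out
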