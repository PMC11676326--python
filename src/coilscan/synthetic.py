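"""Ground-truth fixtures: ideal Crick-parameterized coiled-coil bundles.

A coiled coil is a coil of coils: each chain's C-alpha trace follows a minor
alpha-helix (radius ``R1``, ~102.86 deg/residue for the 3.5-residue heptad
periodicity) whose axis is itself wound around the bundle's superhelical
axis (radius ``R0``, slow frequency ``w0``).  The parametric equations for
residue index ``t`` of one chain are::

    theta = phi0 + w0 * t              (superhelix phase)
    psi   = phi1 + w1 * t              (minor-helix phase, rotating frame)
    x = R0 cos(theta) + R1 [cos(theta) cos(psi) - cos(a) sin(theta) sin(psi)]
    y = R0 sin(theta) + R1 [sin(theta) cos(psi) + cos(a) cos(theta) sin(psi)]
    z = h * t - R1 sin(a) sin(psi)

with rise per residue ``h`` and pitch angle ``a = atan(w0_rad * R0 / h)``.
Because ``psi`` lives in the frame that rotates with the superhelix, a
heptad repeat (``w1 = 720/7`` deg/residue) keeps the same residue positions
facing the bundle core along the whole chain, which is what makes these
bundles exact ground truth for the knobs-into-holes detector.  Chains are
placed at azimuthal steps of 360/n; antiparallel chains are produced by a
proper 180-degree rotation about the radial axis through the chain's mean
azimuth (flipping z while preserving handedness and azimuth), which reverses
the residue index with respect to z exactly.

A pseudo side-chain center is placed 1.5 A radially outward (away from the
minor-helix axis) of each C-alpha; the knobs-into-holes detector consumes
only these centers, so full rotamers are unnecessary.

The module also fabricates complete "prediction runs" for a designed
sequence with labeled regions, producing the exact file layout the divider
emits and the integrator consumes, with controlled pLDDT/PAE and orientation
per region — a stand-in for a real structure-prediction campaign, at desk
scale.  All files produced here are synthetic fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .divide import DivisionManifest, FragmentSpec, build_queries
from .errors import SpecError
from .model_io import FragmentModel, write_model, write_pae

#: default geometric constants for idealized bundles
DEFAULT_R1 = 2.26  # minor helix radius, A
DEFAULT_OMEGA1 = 720.0 / 7.0  # deg/residue: heptad periodicity (3.5 res/turn)
DEFAULT_RISE = 1.51  # A/residue along the superhelix axis
DEFAULT_OMEGA0 = -3.5  # deg/residue: left-handed supercoil
#: superhelix radius by oligomer state, A
DEFAULT_R0 = {1: 4.9, 2: 4.9, 3: 5.8, 4: 6.3}
#: minor-helix phase putting heptad positions a (0) and d (3) symmetrically
#: about the core-facing direction (180 deg in the rotating frame)
DEFAULT_PHI1 = 180.0 + (360.0 - 3.0 * DEFAULT_OMEGA1) / 2.0

SC_RADIAL_OFFSET = 1.5  # A, pseudo side-chain center beyond the C-alpha


@dataclass(frozen=True)
class CrickParams:
    """Geometric parameters of an idealized coiled-coil bundle."""

    n_chains: int = 2
    chain_length: int = 28
    superhelix_radius: float = 4.9  # R0, A
    helix_radius: float = DEFAULT_R1  # R1, A
    superhelix_frequency: float = DEFAULT_OMEGA0  # w0, deg/residue
    minor_helix_frequency: float = DEFAULT_OMEGA1  # w1, deg/residue
    rise_per_residue: float = DEFAULT_RISE  # h, A
    phi0: float = 0.0  # deg
    phi1: float = DEFAULT_PHI1  # deg
    orientations: tuple[int, ...] | None = None  # +1 up / -1 down per chain

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise SpecError("n_chains must be >= 1")
        if self.chain_length < 2:
            raise SpecError("chain_length must be >= 2")
        if self.helix_radius <= 0 or self.superhelix_radius <= 0:
            raise SpecError("radii must be positive")
        if self.helix_radius > self.superhelix_radius:
            raise SpecError(
                f"helix radius {self.helix_radius} exceeds superhelix radius "
                f"{self.superhelix_radius}: chains would overlap the bundle axis"
            )
        if self.rise_per_residue <= 0:
            raise SpecError("rise per residue must be positive")
        if self.orientations is not None:
            if len(self.orientations) != self.n_chains:
                raise SpecError("orientations must list one sign per chain")
            if any(o not in (1, -1) for o in self.orientations):
                raise SpecError("orientations must be +1 or -1")

    @property
    def chain_orientations(self) -> tuple[int, ...]:
        return self.orientations or (1,) * self.n_chains

    @classmethod
    def for_bundle(
        cls, n_chains: int, chain_length: int, parallel: bool = True, **kwargs
    ) -> "CrickParams":
        """Canonical bundle: default radius for the oligomer state; an
        antiparallel bundle alternates chain directions up-down-up-down."""
        r0 = kwargs.pop(
            "superhelix_radius",
            DEFAULT_R0.get(n_chains, DEFAULT_R0[4] + 0.5 * (n_chains - 4)),
        )
        orientations = (1,) * n_chains if parallel else tuple(
            1 if k % 2 == 0 else -1 for k in range(n_chains)
        )
        return cls(
            n_chains=n_chains,
            chain_length=chain_length,
            superhelix_radius=r0,
            orientations=orientations,
            **kwargs,
        )


def _single_chain(params: CrickParams, phi0_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """CA trace and pseudo side-chain centers of one 'up' chain."""
    t = np.arange(params.chain_length, dtype=float)
    r0, r1, h = params.superhelix_radius, params.helix_radius, params.rise_per_residue
    w0 = np.deg2rad(params.superhelix_frequency)
    theta = np.deg2rad(phi0_deg) + w0 * t
    psi = np.deg2rad(params.phi1 + params.minor_helix_frequency * t)
    alpha = np.arctan2(w0 * r0, h)

    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(psi), np.sin(psi)
    x = r0 * ct + r1 * (ct * cp - np.cos(alpha) * st * sp)
    y = r0 * st + r1 * (st * cp + np.cos(alpha) * ct * sp)
    z = h * t - r1 * np.sin(alpha) * sp
    ca = np.column_stack([x, y, z])

    # minor-helix axis point at residue t; side-chain center continues the
    # axis->CA direction a further 1.5 A
    axis = np.column_stack([r0 * ct, r0 * st, h * t])
    radial = ca - axis
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    sc = ca + SC_RADIAL_OFFSET * radial
    return ca, sc


def crick_backbone(params: CrickParams) -> FragmentModel:
    """Generate an idealized bundle as a :class:`FragmentModel`.

    Coordinates only: pLDDT is set to a uniform 100 placeholder and no PAE
    is attached (use :func:`synthesize_prediction` to add confidence data).
    """
    cas, scs = [], []
    n = params.n_chains
    length = params.chain_length
    for k, orient in enumerate(params.chain_orientations):
        phi0_k = params.phi0 + 360.0 * k / n
        ca, sc = _single_chain(params, phi0_k)
        if orient == -1:
            # proper 180-deg rotation about the radial axis through the
            # chain's mean azimuth: z is reversed, azimuth and handedness kept
            beta = np.deg2rad(
                phi0_k + params.superhelix_frequency * (length - 1) / 2.0
            )
            u = np.array([np.cos(beta), np.sin(beta), 0.0])
            rot = 2.0 * np.outer(u, u) - np.eye(3)
            z_mid = 0.5 * (ca[:, 2].min() + ca[:, 2].max())
            ca, sc = ca @ rot.T, sc @ rot.T
            shift = np.array([0.0, 0.0, z_mid - 0.5 * (ca[:, 2].min() + ca[:, 2].max())])
            ca, sc = ca + shift, sc + shift
        cas.append(ca)
        scs.append(sc)
    model = FragmentModel(
        chain_ids=[chr(ord("A") + k) if k < 26 else str(k) for k in range(n)],
        residue_numbers=[np.arange(1, length + 1) for _ in range(n)],
        ca=cas,
        sc_centers=scs,
        plddt=[np.full(length, 100.0) for _ in range(n)],
        provenance={"generator": "crick", "orientations": params.chain_orientations},
    )
    model.validate()
    return model


def add_coordinate_noise(
    model: FragmentModel, sigma: float, rng: np.random.Generator
) -> FragmentModel:
    """Gaussian perturbation (A) of CA and side-chain coordinates."""
    return FragmentModel(
        chain_ids=list(model.chain_ids),
        residue_numbers=[r.copy() for r in model.residue_numbers],
        ca=[c + rng.normal(0.0, sigma, c.shape) for c in model.ca],
        sc_centers=[s + rng.normal(0.0, sigma, s.shape) for s in model.sc_centers],
        plddt=[p.copy() for p in model.plddt],
        pae=None if model.pae is None else model.pae.copy(),
        provenance=dict(model.provenance),
    )


def translate_chains_apart(model: FragmentModel, spacing: float = 100.0) -> FragmentModel:
    """Move chain k by ``k * spacing`` A along x: non-interacting chains."""
    return FragmentModel(
        chain_ids=list(model.chain_ids),
        residue_numbers=[r.copy() for r in model.residue_numbers],
        ca=[c + np.array([k * spacing, 0.0, 0.0]) for k, c in enumerate(model.ca)],
        sc_centers=[s + np.array([k * spacing, 0.0, 0.0]) for k, s in enumerate(model.sc_centers)],
        plddt=[p.copy() for p in model.plddt],
        pae=None if model.pae is None else model.pae.copy(),
        provenance=dict(model.provenance),
    )


def synthesize_prediction(
    model: FragmentModel,
    plddt_profile: float | np.ndarray,
    pae_profile: float | np.ndarray | None,
    pdb_path: str | Path,
    pae_path: str | Path | None = None,
    dialect: str = "predicted_aligned_error",
    wrap_in_list: bool = False,
) -> FragmentModel:
    """Stamp confidence data onto a model and write the prediction artifacts.

    ``plddt_profile`` may be a scalar, a per-residue vector or an
    ``(n_chains, n_residues)`` array; ``pae_profile`` a scalar (constant
    matrix) or a full square matrix.  Returns the stamped in-memory model.
    """
    n, length = model.n_chains, model.n_residues
    prof = np.asarray(plddt_profile, dtype=float)
    if prof.ndim == 0:
        plddt = [np.full(length, float(prof)) for _ in range(n)]
    elif prof.ndim == 1:
        if len(prof) != length:
            raise SpecError(f"pLDDT profile length {len(prof)} != chain length {length}")
        plddt = [prof.copy() for _ in range(n)]
    else:
        if prof.shape != (n, length):
            raise SpecError(f"pLDDT profile shape {prof.shape} != ({n}, {length})")
        plddt = [prof[c].copy() for c in range(n)]

    pae = None
    if pae_profile is not None:
        mat = np.asarray(pae_profile, dtype=float)
        total = n * length
        pae = np.full((total, total), float(mat)) if mat.ndim == 0 else mat
        if pae.shape != (total, total):
            raise SpecError(f"PAE shape {pae.shape} != ({total}, {total})")

    stamped = FragmentModel(
        chain_ids=list(model.chain_ids),
        residue_numbers=[r.copy() for r in model.residue_numbers],
        ca=[c.copy() for c in model.ca],
        sc_centers=[s.copy() for s in model.sc_centers],
        plddt=plddt,
        pae=pae,
        provenance=dict(model.provenance),
    )
    write_model(stamped, pdb_path)
    if pae is not None and pae_path is not None:
        write_pae(pae, pae_path, dialect=dialect, wrap_in_list=wrap_in_list)
    return stamped


# ---------------------------------------------------------------------------
# end-to-end fake prediction runs

#: region kinds with their injected ground truth: sequence motif to repeat,
#: pLDDT level, PAE level (A), and how the bundle is built
REGION_KINDS = {
    "parallel": {"motif": "LKAIEQE", "plddt": 90.0, "pae": 2.0},
    "antiparallel": {"motif": "IEQLKAE", "plddt": 85.0, "pae": 4.0},
    "unstructured": {"motif": "GSSGSEG", "plddt": 40.0, "pae": 20.0},
}

#: ground-truth orientation encoding per region kind (None: no bundle formed,
#: the fake model is non-interacting parallel chains)
REGION_ORIENTATION = {"parallel": 1.0, "antiparallel": 0.0, "unstructured": None}


@dataclass
class FakeRun:
    """A complete synthetic prediction campaign on a designed sequence."""

    rundir: Path
    models_dir: Path
    manifest: DivisionManifest
    labels: list[str]  # ground-truth region kind per full-length position
    seed: int
    plddt_by_region: dict[str, float] = field(
        default_factory=lambda: {k: v["plddt"] for k, v in REGION_KINDS.items()}
    )


def design_sequence(layout: Sequence[tuple[str, int]]) -> tuple[str, list[str]]:
    """Designed sequence for a region layout [(kind, length), ...]."""
    seq_parts: list[str] = []
    labels: list[str] = []
    for kind, length in layout:
        if kind not in REGION_KINDS:
            raise SpecError(f"unknown region kind {kind!r}, expected {sorted(REGION_KINDS)}")
        if length < 1:
            raise SpecError("region lengths must be >= 1")
        motif = REGION_KINDS[kind]["motif"]
        seq_parts.append((motif * (length // len(motif) + 1))[:length])
        labels.extend([kind] * length)
    return "".join(seq_parts), labels


def _fragment_model_for_kind(
    kind: str, n_chains: int, chain_length: int, rng: np.random.Generator,
    coord_noise: float,
) -> FragmentModel:
    if kind == "antiparallel" and n_chains >= 2:
        params = CrickParams.for_bundle(n_chains, chain_length, parallel=False)
        model = crick_backbone(params)
    else:
        params = CrickParams.for_bundle(n_chains, chain_length, parallel=True)
        model = crick_backbone(params)
        if kind == "unstructured":
            model = translate_chains_apart(model)
    if coord_noise > 0:
        model = add_coordinate_noise(model, coord_noise, rng)
    return model


def build_fake_run(
    layout: Sequence[tuple[str, int]],
    specs: Sequence[str | FragmentSpec],
    seed: int,
    outdir: str | Path,
    sequence_id: str = "synthetic",
    flank: str = "",
    coord_noise: float = 0.1,
    plddt_jitter: float = 0.25,
    pae_dialect: str = "predicted_aligned_error",
) -> FakeRun:
    """Fabricate a full run: division artifacts plus one model per fragment.

    Each fragment receives a bundle built for the majority ground-truth
    label of its window (ties resolved toward the earlier region), with the
    region's pLDDT level (jittered) and a constant PAE at the region's
    level.  Deterministic given ``seed``: identical seeds give
    byte-identical run directories.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    sequence, labels = design_sequence(layout)
    manifest = build_queries(sequence, specs, sequence_id=sequence_id, flank=flank)
    manifest.write(outdir)

    # record the seed in the run's parameter file
    params_path = outdir / "parameters.json"
    params = json.loads(params_path.read_text())
    params["seed"] = int(seed)
    params_path.write_text(json.dumps(params, indent=2, sort_keys=True) + "\n")

    models_dir = outdir / "models"
    models_dir.mkdir(exist_ok=True)
    kind_order = [k for k, _ in layout]
    for spec in manifest.specs:
        for w in manifest.windows[spec.label]:
            window_labels = labels[w.start:w.end]
            counts = {k: window_labels.count(k) for k in set(window_labels)}
            best = max(counts.values())
            kind = next(  # tie-break: earliest region in the layout
                k for k in kind_order if counts.get(k, 0) == best
            )
            chain_length = len(w.query_sequence)
            model = _fragment_model_for_kind(
                kind, spec.n_copies, chain_length, rng, coord_noise
            )
            info = REGION_KINDS[kind]
            plddt = np.clip(
                rng.normal(info["plddt"], plddt_jitter, (spec.n_copies, chain_length)),
                0.0, 100.0,
            )
            stem = manifest.query_file(spec.label, w.fragment_index)[: -len(".fasta")]
            synthesize_prediction(
                model,
                plddt,
                info["pae"],
                models_dir / f"{stem}.pdb",
                models_dir / f"{stem}.pae.json",
                dialect=pae_dialect,
            )

    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "labels": labels,
                "plddt_by_region": {k: v["plddt"] for k, v in REGION_KINDS.items()},
                "orientation_by_region": REGION_ORIENTATION,
                "seed": int(seed),
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")

    return FakeRun(
        rundir=outdir, models_dir=models_dir, manifest=manifest,
        labels=labels, seed=int(seed),
    )
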