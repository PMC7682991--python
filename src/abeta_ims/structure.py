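"""Fibril cropping and projection-approximation (PA) theoretical CCS.

Fibril structures (e.g. PDB entries 5OQV, 2NAO — dimer-base Aβ42 fibrils)
are cropped into two oligomer series: monomer-based (MB, consecutive layers
of a single protofilament) and dimer-based (DB, consecutive layers of the
paired two-monomer unit).  Each cropped oligomer gets a theoretical CCS via
the projection approximation: the orientation-averaged shadow area of the
atoms modeled as hard disks of radius r_vdw + r_gas.  PA is exactly
verifiable analytically (a single atom projects to pi*(r_vdw+r_gas)^2) and
suffices for the slope/intercept comparison the growth analysis needs;
trajectory-method CCS is out of scope.  Crops are used as-is; externally
relaxed coordinates can be read back through :func:`read_structure`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .growth import CCSSeries

#: Van der Waals radii (Å), Bondi (1964) set; single bundled table.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}

#: Default effective buffer-gas radius (Å) for an N2-like gas.
DEFAULT_GAS_RADIUS = 1.5


@dataclass
class Structure:
    """Atoms of one model: element symbols, coordinates (Å), chain ids,
    residue indices."""

    elements: list[str]
    coords: np.ndarray  # (N, 3)
    chains: list[str]
    residues: list[int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for el in set(self.elements):
            if el.upper() not in VDW_RADII:
                raise ValueError(f"unknown element {el!r}: no radius available")

    def __len__(self) -> int:
        return len(self.elements)

    def radii(self, gas_radius: float = 0.0) -> np.ndarray:
        return np.array(
            [VDW_RADII[el.upper()] + gas_radius for el in self.elements]
        )

    def subset(self, mask: np.ndarray, note: str = "") -> "Structure":
        idx = np.flatnonzero(mask)
        return Structure(
            elements=[self.elements[i] for i in idx],
            coords=self.coords[idx],
            chains=[self.chains[i] for i in idx],
            residues=[self.residues[i] for i in idx],
            provenance={**self.provenance, "crop": note},
        )


def read_structure(
    pdb_text_or_path,
    model: int = 1,
    include_hetero: bool = False,
) -> Structure:
    """Parse a PDB file or text into a :class:`Structure` (one model).

    Heteroatoms are excluded by default; a missing model or an element with
    no radius entry raises."""
    import gemmi

    text = str(pdb_text_or_path)
    if "\nATOM" in text or text.startswith(("ATOM", "HEADER", "CRYST1", "MODEL")):
        st = gemmi.read_pdb_string(text)
        source = "<string>"
    else:
        st = gemmi.read_pdb(text)
        source = text
    st.setup_entities()
    models = {i + 1: m for i, m in enumerate(st)}
    if model not in models:
        raise ValueError(f"model {model} not present (file has {len(models)})")
    elements, coords, chains, residues = [], [], [], []
    for chain in models[model]:
        for res in chain:
            if not include_hetero and res.het_flag == "H":
                continue
            for atom in res:
                symbol = atom.element.name.upper()
                if symbol in ("", "X"):
                    raise ValueError(
                        f"unknown element for atom {atom.name} in residue "
                        f"{res.name} {res.seqid.num}"
                    )
                elements.append(symbol)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                chains.append(chain.name)
                residues.append(res.seqid.num)
    if not elements:
        raise ValueError("no atoms parsed")
    return Structure(
        elements=elements,
        coords=np.array(coords),
        chains=chains,
        residues=residues,
        provenance={"file": source, "model": model},
    )


def crop_oligomer(
    fibril: Structure,
    n: int,
    base: str,
    layer_map: dict[str, dict],
) -> Structure:
    """Crop an n-monomer oligomer out of a fibril structure.

    ``layer_map`` maps chain id -> {"layer": int, "protofilament": 0|1}.
    MB: n consecutive layers of protofilament 0.  DB: consecutive layers of
    the paired two-monomer unit; odd n takes ceil(n/2) layers with one
    unpaired monomer (flagged in provenance).
    """
    if base not in ("MB", "DB"):
        raise ValueError("base must be 'MB' or 'DB'")
    if n < 1:
        raise ValueError("oligomer order must be >= 1")
    by_layer: dict[int, dict[int, str]] = {}
    for chain_id, info in layer_map.items():
        by_layer.setdefault(info["layer"], {})[info.get("protofilament", 0)] = chain_id
    layers = sorted(by_layer)

    selected: list[str] = []
    note = f"{base} {n}-mer"
    if base == "MB":
        available = [by_layer[l][0] for l in layers if 0 in by_layer[l]]
        if n > len(available):
            raise ValueError(
                f"requested {n} layers but only {len(available)} available"
            )
        selected = available[:n]
    else:
        paired = [
            (by_layer[l][0], by_layer[l][1])
            for l in layers
            if 0 in by_layer[l] and 1 in by_layer[l]
        ]
        n_layers = math.ceil(n / 2)
        if n_layers > len(paired):
            raise ValueError(
                f"requested {n} monomers ({n_layers} layers) but only "
                f"{len(paired)} paired layers available"
            )
        for a, b in paired[:n_layers]:
            selected.extend([a, b])
        if n % 2:
            selected = selected[:-1]  # drop the unpaired partner
            note += " (odd: one unpaired monomer)"
    chain_set = set(selected)
    mask = np.array([c in chain_set for c in fibril.chains])
    return fibril.subset(mask, note)


@dataclass
class PAResult:
    """Monte-Carlo projection-approximation CCS."""

    ccs_a2: float
    mc_se_a2: float
    n_orientations: int
    n_rays: int
    gas_radius: float
    seed: int

    def __post_init__(self) -> None:
        if self.ccs_a2 <= 0:
            raise ValueError("CCS must be positive")


def pa_ccs(
    s: Structure,
    gas_radius: float = DEFAULT_GAS_RADIUS,
    n_orientations: int = 300,
    n_rays_per_orientation: int = 5000,
    seed: int = 0,
) -> PAResult:
    """Projection-approximation CCS by Monte-Carlo orientation averaging.

    For each quaternion-uniform random orientation, the structure is
    projected onto a plane and the area of the union of disks (radius =
    vdW + gas radius) is estimated by hit-or-miss sampling inside the
    projected bounding box.  The standard error is the spread of the
    per-orientation areas over sqrt(orientations).
    """
    if len(s) < 1:
        raise ValueError("structure has no atoms")
    if n_orientations < 1 or n_rays_per_orientation < 1:
        raise ValueError("sampling counts must be positive")
    rng = np.random.default_rng(seed)
    radii = s.radii(gas_radius)
    r_max = float(radii.max())
    centered = s.coords - s.coords.mean(axis=0)
    unique_r = np.unique(radii)
    areas = np.empty(n_orientations)
    rotations = Rotation.random(n_orientations, random_state=rng)
    for i in range(n_orientations):
        xy = rotations[i].apply(centered)[:, :2]
        lo = (xy - radii[:, None]).min(axis=0)
        hi = (xy + radii[:, None]).max(axis=0)
        box = hi - lo
        pts = lo + rng.random((n_rays_per_orientation, 2)) * box
        hit = np.zeros(len(pts), dtype=bool)
        for r in unique_r:
            group = xy[radii == r]
            tree = cKDTree(group)
            counts = tree.query_ball_point(pts[~hit], r, return_length=True)
            sub = np.zeros(len(pts), dtype=bool)
            sub[np.flatnonzero(~hit)] = counts > 0
            hit |= sub
        areas[i] = box[0] * box[1] * hit.mean()
    ccs = float(areas.mean())
    se = float(areas.std(ddof=1) / math.sqrt(n_orientations)) if n_orientations > 1 else 0.0
    # hit-or-miss sampling noise floor (single-orientation case)
    if n_orientations == 1:
        p = max(min(ccs / (box[0] * box[1]), 1.0), 0.0)
        se = float(box[0] * box[1] * math.sqrt(p * (1 - p) / n_rays_per_orientation))
    return PAResult(
        ccs_a2=ccs,
        mc_se_a2=se,
        n_orientations=n_orientations,
        n_rays=n_rays_per_orientation,
        gas_radius=gas_radius,
        seed=seed,
    )


def ccs_series_from_fibril(
    fibril: Structure,
    base: str,
    n_range,
    layer_map: dict[str, dict],
    gas_radius: float = DEFAULT_GAS_RADIUS,
    n_orientations: int = 300,
    n_rays_per_orientation: int = 5000,
    seed: int = 0,
) -> CCSSeries:
    """PA CCS for each cropped oligomer, assembled into a growth-analysis
    series (Monte-Carlo standard errors as sigma)."""
    orders = sorted(n_range)
    ccs_values, sigmas = [], []
    for n in orders:
        crop = crop_oligomer(fibril, n, base, layer_map)
        result = pa_ccs(
            crop,
            gas_radius=gas_radius,
            n_orientations=n_orientations,
            n_rays_per_orientation=n_rays_per_orientation,
            seed=seed + n,
        )
        ccs_values.append(result.ccs_a2)
        sigmas.append(result.mc_se_a2)
    return CCSSeries(
        n=np.array(orders),
        ccs_a2=np.array(ccs_values),
        sigma=np.array(sigmas),
        tag=base,
    )
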