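"""Representative-atom reduction of macromolecular structures.

Every downstream computation in this package operates on one point per
polymer residue: the C-alpha atom of an amino acid or the backbone phosphorus
of a nucleotide, weighted by the average residue mass.  Waters, ligands and
ions are excluded.  PDB and mmCIF files are read through biotite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RepresentativeAtomSet",
    "residue_mass",
    "residue_sigma",
    "load_representative_atoms",
    "write_representative_pdb",
    "EmptySelectionError",
]


class EmptySelectionError(ValueError):
    """Raised when a chain/assembly selector matches no polymer residue."""


# Average residue masses in Daltons (amino acid / nucleotide minus water,
# i.e. the mass contributed to a polymer chain).
AMINO_ACID_MASSES = {
    "GLY": 57.0519, "ALA": 71.0788, "SER": 87.0782, "PRO": 97.1167,
    "VAL": 99.1326, "THR": 101.1051, "CYS": 103.1388, "LEU": 113.1594,
    "ILE": 113.1594, "ASN": 114.1038, "ASP": 115.0886, "GLN": 128.1307,
    "LYS": 128.1741, "GLU": 129.1155, "MET": 131.1926, "HIS": 137.1411,
    "PHE": 147.1766, "ARG": 156.1875, "TYR": 163.1760, "TRP": 186.2132,
}

NUCLEOTIDE_MASSES = {
    "A": 329.2059, "C": 305.1808, "G": 345.2049, "U": 306.1653,
    "DA": 313.2066, "DC": 289.1815, "DG": 329.2056, "DT": 304.1960,
}

#: Fallback for unknown residue codes: the unweighted mean amino-acid
#: residue mass of the 20-entry table above.
DEFAULT_RESIDUE_MASS = float(np.mean(list(AMINO_ACID_MASSES.values())))

# Modified residues mapped to their parent standard residue.
MODIFIED_PARENT = {
    "MSE": "MET", "SEP": "SER", "TPO": "THR", "PTR": "TYR",
    "CSO": "CYS", "HYP": "PRO", "MLY": "LYS", "KCX": "LYS",
    "CME": "CYS", "PCA": "GLU",
}

# Average residue volumes in cubic Angstrom (partial volumes of amino-acid
# residues in solution; nucleotides assigned a common coarse value).  Used to
# derive the per-residue Gaussian width of the density model: a residue is
# modelled as a single isotropic Gaussian whose per-axis variance matches the
# second moment of a uniform sphere of the residue's volume,
# sigma = R / sqrt(5) with R = (3 V / 4 pi)^(1/3).
RESIDUE_VOLUMES = {
    "GLY": 60.1, "ALA": 88.6, "SER": 89.0, "CYS": 108.5, "ASP": 111.1,
    "THR": 116.1, "ASN": 114.1, "PRO": 112.7, "GLU": 138.4, "VAL": 140.0,
    "GLN": 143.8, "HIS": 153.2, "MET": 162.9, "ILE": 166.7, "LEU": 166.7,
    "LYS": 168.6, "ARG": 173.4, "PHE": 189.9, "TYR": 193.6, "TRP": 227.8,
    "A": 300.0, "C": 285.0, "G": 310.0, "U": 290.0,
    "DA": 300.0, "DC": 285.0, "DG": 310.0, "DT": 295.0,
}

DEFAULT_RESIDUE_VOLUME = float(np.mean([RESIDUE_VOLUMES[k] for k in AMINO_ACID_MASSES]))


def residue_mass(residue_code: str) -> float:
    """Average mass in Daltons contributed by a residue to a polymer.

    Total function: three-letter amino-acid codes and one/two-letter
    nucleotide codes resolve through the embedded tables, known modified
    residues map to their parent, anything else returns
    :data:`DEFAULT_RESIDUE_MASS`.
    """
    code = residue_code.strip().upper()
    code = MODIFIED_PARENT.get(code, code)
    if code in AMINO_ACID_MASSES:
        return AMINO_ACID_MASSES[code]
    if code in NUCLEOTIDE_MASSES:
        return NUCLEOTIDE_MASSES[code]
    return DEFAULT_RESIDUE_MASS


def residue_sigma(residue_code: str) -> float:
    """Gaussian width (A) of the single-Gaussian residue density model."""
    code = residue_code.strip().upper()
    code = MODIFIED_PARENT.get(code, code)
    vol = RESIDUE_VOLUMES.get(code, DEFAULT_RESIDUE_VOLUME)
    radius = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
    return radius / np.sqrt(5.0)


@dataclass
class RepresentativeAtomSet:
    """Weighted 3D point set standing in for residues.

    coordinates : (N, 3) float array, Angstrom
    masses : (N,) strictly positive float array, Daltons
    labels : list of (chain_id, residue_id, residue_name) tuples
    source_id : free-text provenance tag
    """

    coordinates: np.ndarray
    masses: np.ndarray
    labels: list = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self):
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        self.masses = np.asarray(self.masses, dtype=float)
        if self.coordinates.shape[0] == 0:
            raise ValueError("at least one representative atom is required")
        if self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (N, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.masses.shape != (self.coordinates.shape[0],):
            raise ValueError("masses must match coordinates in length")
        if not np.all(self.masses > 0):
            raise ValueError("masses must be strictly positive")
        if not self.labels:
            self.labels = [("A", i + 1, "UNK") for i in range(len(self.masses))]
        if len(self.labels) != len(self.masses):
            raise ValueError("labels must match coordinates in length")

    def __len__(self) -> int:
        return self.coordinates.shape[0]

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.coordinates / self.total_mass

    def gyration_radius(self) -> float:
        d2 = np.sum((self.coordinates - self.center_of_mass()) ** 2, axis=1)
        return float(np.sqrt(self.masses @ d2 / self.total_mass))

    def sigmas(self) -> np.ndarray:
        return np.array([residue_sigma(name) for _, _, name in self.labels])

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "RepresentativeAtomSet":
        """Copy with coordinates mapped through x -> R x + t."""
        coords = self.coordinates
        if rotation is not None:
            coords = coords @ np.asarray(rotation).T
        if translation is not None:
            coords = coords + np.asarray(translation)
        return RepresentativeAtomSet(coords, self.masses.copy(),
                                     list(self.labels), self.source_id)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif", ".pdbx"):
        return "mmcif"
    return "pdb"


def load_representative_atoms(path, format: str | None = None,
                              chains: list[str] | None = None,
                              assembly: str | None = None) -> RepresentativeAtomSet:
    """Reduce a PDB/mmCIF file to its representative-atom point set.

    One point per amino-acid residue with a C-alpha atom and per nucleotide
    with a backbone phosphorus; masses from :func:`residue_mass`.  ``chains``
    restricts the selection; ``assembly`` expands the named biological
    assembly instead of using the asymmetric unit as deposited (the default).
    Residues lacking their representative atom are skipped with a warning.
    """
    import biotite.structure as struc

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "pdb":
            from biotite.structure.io.pdb import PDBFile, get_assembly, get_structure

            pdb_file = PDBFile.read(str(path))
            if assembly is not None:
                array = get_assembly(pdb_file, assembly_id=assembly, model=1,
                                     altloc="occupancy")
            else:
                array = get_structure(pdb_file, model=1, altloc="occupancy")
        elif fmt == "mmcif":
            from biotite.structure.io.pdbx import CIFFile, get_assembly, get_structure

            cif_file = CIFFile.read(str(path))
            if assembly is not None:
                array = get_assembly(cif_file, assembly_id=assembly, model=1,
                                     altloc="occupancy")
            else:
                array = get_structure(cif_file, model=1, altloc="occupancy")
        else:
            raise ValueError(f"unknown format: {fmt!r}")

    if chains is not None:
        array = array[np.isin(array.chain_id, list(chains))]
        if array.array_length() == 0:
            raise EmptySelectionError(f"no atoms in chains {chains!r}")

    amino = struc.filter_amino_acids(array)
    nucleic = struc.filter_nucleotides(array)
    is_ca = amino & (array.atom_name == "CA") & (array.element == "C")
    is_p = nucleic & (array.atom_name == "P") & (array.element == "P")
    rep = array[is_ca | is_p]
    if rep.array_length() == 0:
        raise EmptySelectionError(f"no representative atoms selected in {path.name}")

    # first occurrence wins for duplicated residues (microheterogeneity)
    seen = set()
    keep = np.ones(rep.array_length(), dtype=bool)
    for i in range(rep.array_length()):
        key = (rep.chain_id[i], int(rep.res_id[i]), str(rep.ins_code[i]))
        if key in seen:
            keep[i] = False
        seen.add(key)
    rep = rep[keep]

    n_polymer_res = struc.get_residue_count(array[amino | nucleic])
    if rep.array_length() < n_polymer_res:
        logger.warning(
            "%s: %d polymer residue(s) lack a representative atom and were skipped",
            path.name, n_polymer_res - rep.array_length(),
        )

    labels = [
        (str(rep.chain_id[i]), int(rep.res_id[i]), str(rep.res_name[i]))
        for i in range(rep.array_length())
    ]
    masses = np.array([residue_mass(name) for _, _, name in labels])
    return RepresentativeAtomSet(rep.coord.astype(float), masses, labels,
                                 source_id=path.stem)


def write_representative_pdb(atoms: RepresentativeAtomSet, path) -> None:
    """Write the point set as a minimal C-alpha-only PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(atoms)
    array = struc.AtomArray(n)
    array.coord = atoms.coordinates.astype(np.float32)
    array.chain_id = np.array([str(c)[:4] for c, _, _ in atoms.labels])
    array.res_id = np.array([int(r) for _, r, _ in atoms.labels])
    array.res_name = np.array([str(nm)[:5] for _, _, nm in atoms.labels])
    array.atom_name = np.array(["CA"] * n)
    array.element = np.array(["C"] * n)
    array.hetero = np.zeros(n, dtype=bool)
    pdb_file = PDBFile()
    pdb_file.set_structure(array)
    pdb_file.write(str(path))
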