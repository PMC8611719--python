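"""Molecule preparation: loading, standardization, filtering and deduplication.

Implements the preprocessing stages applied to every input data set before
fragment search: parsing, mixture resolution (largest nonlinear organic
component), iterative sugar removal, physicochemical filters, structure
standardization (isotopes, functional groups, charges, tautomer, stereo),
Murcko scaffold extraction for fragment sets, a per-molecule wall-clock
timeout, and cross-chunk deduplication on stereo-free InChIKeys.
"""

from __future__ import annotations

import fcntl
import math
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional, Sequence

import yaml
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

#: Elements retained by default; everything else marks a record for removal.
DEFAULT_ELEMENTS = frozenset({"H", "B", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"})


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds controlling molecule filtering and classification.

    Defaults mirror a standard natural-product preprocessing protocol:
    at least 4 heavy atoms, at most 1000 Da, at least one ring, a fixed
    organic element whitelist, a 10 s standardization timeout, at most 3
    linker atoms between two fragments before the pair is discarded, and
    at most 5 overlapping fragment pairs per molecule.
    """

    min_heavy_atoms: int = 4
    max_mol_weight: float = 1000.0
    min_rings: int = 1
    allowed_elements: frozenset[str] = DEFAULT_ELEMENTS
    timeout_seconds: float = 10.0
    linker_cutoff: int = 3
    max_overlaps: int = 5

    def __post_init__(self) -> None:
        for name in ("min_heavy_atoms", "max_mol_weight", "min_rings",
                     "timeout_seconds", "linker_cutoff", "max_overlaps"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "allowed_elements" in data:
            data["allowed_elements"] = frozenset(data["allowed_elements"])
        return cls(**data)


@dataclass
class MoleculeRecord:
    """One input structure together with its processing status.

    ``identity_key`` is the stereo-free InChIKey of the standardized
    structure and is only defined for records with ``status == "passed"``;
    every non-passed record carries the name of the task that removed it
    in ``removal_reason``.
    """

    record_id: str
    mol: Optional[Chem.Mol]
    status: str = "passed"  # passed | filtered | error | timeout
    removal_reason: Optional[str] = None
    identity_key: Optional[str] = None
    provenance: tuple[str, int] = ("", -1)

    def fail(self, status: str, reason: str) -> "MoleculeRecord":
        self.status = status
        self.removal_reason = reason
        self.identity_key = None
        return self


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_molecules(path: str | Path, fmt: str) -> Iterator[MoleculeRecord]:
    """Stream records from an SDF or SMILES file in file order.

    Unparsable entries yield records with ``status="error"`` and
    ``removal_reason="parse"`` instead of being silently dropped; records
    with an empty structure are filtered with reason ``"empty"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
        for idx, mol in enumerate(supplier):
            rec_id = None
            if mol is not None and mol.HasProp("_Name") and mol.GetProp("_Name").strip():
                rec_id = mol.GetProp("_Name").strip()
            rec_id = rec_id or f"{path.stem}_{idx}"
            rec = MoleculeRecord(rec_id, mol, provenance=(str(path), idx))
            if mol is None:
                rec.fail("error", "parse")
            elif mol.GetNumAtoms() == 0:
                rec.fail("filtered", "empty")
            yield rec
    elif fmt == "smiles":
        with open(path) as fh:
            for idx, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                smi = parts[0]
                rec_id = parts[1] if len(parts) > 1 else f"{path.stem}_{idx}"
                mol = Chem.MolFromSmiles(smi)
                rec = MoleculeRecord(rec_id, mol, provenance=(str(path), idx))
                if mol is None:
                    rec.fail("error", "parse")
                elif mol.GetNumAtoms() == 0:
                    rec.fail("filtered", "empty")
                yield rec
    else:
        raise ValueError(f"unknown format: {fmt!r}")


# ---------------------------------------------------------------------------
# Mixtures
# ---------------------------------------------------------------------------

_METAL_DISCONNECTOR = rdMolStandardize.MetalDisconnector()


def _component_rank(mol: Chem.Mol) -> tuple:
    has_carbon = any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())
    try:
        n_rings = mol.GetRingInfo().NumRings()
    except RuntimeError:  # fragments skip sanitization; perceive rings now
        Chem.FastFindRings(mol)
        n_rings = mol.GetRingInfo().NumRings()
    has_ring = n_rings > 0
    return (has_carbon, has_ring, mol.GetNumHeavyAtoms())


def select_main_component(mol: Chem.Mol) -> Chem.Mol:
    """Resolve a mixture to its preferred component.

    Metal-nonmetal bonds are cut first; among the resulting components the
    winner is chosen by (1) organic (contains carbon), (2) contains a ring,
    (3) heavy atom count, with canonical-SMILES lexicographic order as the
    deterministic tie-break.
    """
    mol = _METAL_DISCONNECTOR.Disconnect(mol)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol
    # maximize rank; ties resolved by smallest canonical SMILES
    best = max(frags, key=lambda f: (_component_rank(f), _neg_smiles(f)))
    return best


class _neg_smiles(str):
    """Canonical SMILES ordered in reverse, so max() prefers the smallest."""

    def __new__(cls, mol: Chem.Mol):
        return super().__new__(cls, Chem.MolToSmiles(mol))

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# Sugar removal
# ---------------------------------------------------------------------------

def _is_sugar_like_ring(mol: Chem.Mol, ring: Sequence[int]) -> bool:
    """A 5/6-membered saturated ring with one ring oxygen where at least
    (size - 2) ring carbons bear an exocyclic single-bonded oxygen."""
    if len(ring) not in (5, 6):
        return False
    ring_set = set(ring)
    n_oxygen = 0
    n_exo_oxy_carbons = 0
    for idx in ring:
        atom = mol.GetAtomWithIdx(idx)
        if atom.GetIsAromatic():
            return False
        if atom.GetAtomicNum() == 8:
            n_oxygen += 1
            continue
        if atom.GetAtomicNum() != 6:
            return False
        for nbr in atom.GetNeighbors():
            if nbr.GetIdx() in ring_set or nbr.GetAtomicNum() != 8:
                continue
            bond = mol.GetBondBetweenAtoms(idx, nbr.GetIdx())
            if bond.GetBondType() == Chem.BondType.SINGLE:
                n_exo_oxy_carbons += 1
                break
    if n_oxygen != 1:
        return False
    # all ring bonds single
    for i, idx in enumerate(ring):
        bond = mol.GetBondBetweenAtoms(idx, ring[(i + 1) % len(ring)])
        if bond is not None and bond.GetBondType() != Chem.BondType.SINGLE:
            return False
    return n_exo_oxy_carbons >= len(ring) - 2


def _peel_one_sugar(mol: Chem.Mol) -> Optional[Chem.Mol]:
    """Remove one terminal sugar-like ring, or return None if none applies.

    The ring together with its small exocyclic substituents (OH, CH2OH
    style branches of at most two heavy atoms) is deleted; the molecule
    must stay connected afterwards, i.e. at most one remaining component is
    larger than a substituent, and that aglycone must be attached through a
    glycosidic C-O bond whose oxygen is kept as a hydroxyl.
    """
    ri = mol.GetRingInfo()
    n_atoms = mol.GetNumAtoms()
    for ring in ri.AtomRings():
        if not _is_sugar_like_ring(mol, ring):
            continue
        ring_set = set(ring)
        rest = set(range(n_atoms)) - ring_set
        if not rest:
            return Chem.RWMol().GetMol()  # molecule entirely sugar
        # connected components of the molecule minus the ring
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(rest)
        for bond in mol.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if i in rest and j in rest:
                g.add_edge(i, j)
        comps = [set(c) for c in nx.connected_components(g)]
        substituents, aglycones = [], []
        for comp in comps:
            if len(comp) <= 2 and all(
                mol.GetAtomWithIdx(i).GetAtomicNum() in (6, 8) for i in comp
            ) and not any(mol.GetAtomWithIdx(i).IsInRing() for i in comp):
                substituents.append(comp)
            else:
                aglycones.append(comp)
        if len(aglycones) > 1:
            continue  # inner ring; becomes terminal in a later iteration
        if aglycones:
            aglycone = aglycones[0]
            # attachment must be a glycosidic oxygen bonded to a ring carbon
            attach_ok = False
            for idx in ring:
                if mol.GetAtomWithIdx(idx).GetAtomicNum() != 6:
                    continue
                for nbr in mol.GetAtomWithIdx(idx).GetNeighbors():
                    if nbr.GetIdx() in aglycone and nbr.GetAtomicNum() == 8:
                        attach_ok = True
            if not attach_ok:
                continue
            keep = aglycone
        else:
            keep = set()
        rw = Chem.RWMol(mol)
        for idx in sorted(set(range(n_atoms)) - keep, reverse=True):
            rw.RemoveAtom(idx)
        out = rw.GetMol()
        try:
            Chem.SanitizeMol(out)
        except Exception:
            continue
        return out
    return None


def remove_sugars(mol: Chem.Mol) -> Chem.Mol:
    """Iteratively peel terminal sugar-like rings, outer layer first.

    Terminates because every peel strictly decreases the ring count. A
    molecule that is entirely sugar collapses to an empty structure, which
    the downstream filters then remove.
    """
    while True:
        peeled = _peel_one_sugar(mol)
        if peeled is None:
            return mol
        mol = peeled
        if mol.GetNumAtoms() == 0:
            return mol


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def apply_filters(mol: Chem.Mol, cfg: FilterConfig) -> tuple[bool, Optional[str]]:
    """Check filters in fixed order and report the first violated rule."""
    if mol.GetNumHeavyAtoms() < cfg.min_heavy_atoms:
        return False, "num_heavy_atoms"
    if Descriptors.MolWt(mol) > cfg.max_mol_weight:
        return False, "molecular_weight"
    if mol.GetRingInfo().NumRings() < cfg.min_rings:
        return False, "num_rings"
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in cfg.allowed_elements:
            return False, "elements"
    return True, None


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

_NORMALIZER = rdMolStandardize.Normalizer()
_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMERIZER = rdMolStandardize.TautomerEnumerator()


def standardize_structure(mol: Chem.Mol) -> Chem.Mol:
    """Standardize a structure; the result is a fixpoint of this function.

    Order of operations: isotope reset, functional group normalization,
    charge neutralization, canonical tautomer, stereo removal, and a final
    round-trip through canonical SMILES.
    """
    mol = Chem.Mol(mol)
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    mol = _NORMALIZER.normalize(mol)
    mol = _UNCHARGER.uncharge(mol)
    mol = _TAUTOMERIZER.Canonicalize(mol)
    Chem.RemoveStereochemistry(mol)
    out = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    if out is None:
        raise ValueError("standardization produced an unparsable structure")
    return out


def extract_murcko(mol: Chem.Mol) -> Chem.Mol:
    """Murcko scaffold: ring systems plus linkers, side chains pruned,
    followed by another round of charge removal."""
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold.GetNumAtoms() > 0:
        scaffold = _UNCHARGER.uncharge(scaffold)
    return scaffold


def identity_key(mol: Chem.Mol) -> str:
    """Stereo-free InChIKey of a standardized structure (27 characters)."""
    return Chem.MolToInchiKey(mol)


def run_with_timeout(
    task: Callable[[MoleculeRecord], MoleculeRecord],
    record: MoleculeRecord,
    limit: Optional[float],
) -> MoleculeRecord:
    """Run ``task`` and mark the record as timed out if it exceeds ``limit``
    seconds of wall-clock time. ``limit=None`` or infinity disables the check.

    The check is cooperative: the task runs to completion and the elapsed
    time is compared afterwards, so bookkeeping stays reproducible without
    forcibly interrupting native code.
    """
    if limit is not None and not math.isinf(limit) and limit <= 0:
        raise ValueError("timeout limit must be positive")
    start = time.monotonic()
    try:
        result = task(record)
    except Exception:
        return record.fail("error", "standardize")
    elapsed = time.monotonic() - start
    if limit is not None and not math.isinf(limit) and elapsed > limit:
        return record.fail("timeout", "timeout")
    return result


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

class KeyStore:
    """Persistent identity-key set guarding cross-chunk deduplication.

    Backed by a plain text file (one InChIKey per line) updated under an
    exclusive advisory lock; the lock scope covers the whole
    read-check-append cycle so two concurrent chunks can never both claim
    the same key. ``path=None`` gives a purely in-memory store.
    """

    def __init__(self, path: Optional[str | Path] = None):
        self.path = Path(path) if path is not None else None
        self._mem: set[str] = set()
        if self.path is not None and self.path.exists():
            try:
                self._read_keys()
            except OSError as exc:
                raise RuntimeError(f"corrupt dedup store {self.path}: {exc}")

    def _read_keys(self) -> set[str]:
        keys = set()
        with open(self.path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    keys.add(line)
        return keys

    def claim(self, keys: Sequence[str]) -> set[str]:
        """Atomically claim keys; returns the subset that was new."""
        if self.path is None:
            new = []
            for k in keys:
                if k not in self._mem:
                    self._mem.add(k)
                    new.append(k)
            return set(new)
        lock_path = self.path.with_suffix(self.path.suffix + ".lock")
        with open(lock_path, "w") as lock_fh:
            fcntl.flock(lock_fh, fcntl.LOCK_EX)
            try:
                existing = self._read_keys() if self.path.exists() else set()
                new = []
                for k in keys:
                    if k not in existing:
                        existing.add(k)
                        new.append(k)
                with open(self.path, "a") as fh:
                    for k in new:
                        fh.write(k + "\n")
                return set(new)
            finally:
                fcntl.flock(lock_fh, fcntl.LOCK_UN)


def deduplicate(
    records: Iterable[MoleculeRecord], store: Optional[KeyStore] = None
) -> Iterator[MoleculeRecord]:
    """Keep the first occurrence of every identity key, in processing order.

    Later occurrences — within this stream or already claimed in the store
    by another chunk — are marked ``filtered`` with reason ``"duplicate"``.
    """
    store = store if store is not None else KeyStore()
    for rec in records:
        if rec.status != "passed":
            yield rec
            continue
        claimed = store.claim([rec.identity_key])
        if rec.identity_key not in claimed:
            rec.fail("filtered", "duplicate")
        yield rec


# ---------------------------------------------------------------------------
# Full preparation pipeline
# ---------------------------------------------------------------------------

def _standardize_record(rec: MoleculeRecord, cfg: FilterConfig, mode: str) -> MoleculeRecord:
    mol = select_main_component(rec.mol)
    if not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()):
        return rec.fail("filtered", "inorganic")
    if mode == "molecules":
        mol = remove_sugars(mol)
        if mol.GetNumAtoms() == 0:
            return rec.fail("filtered", "empty")
        ok, reason = apply_filters(mol, cfg)
        if not ok:
            return rec.fail("filtered", reason)
    mol = standardize_structure(mol)
    if mode == "fragments":
        mol = extract_murcko(mol)
        if mol.GetNumAtoms() == 0:
            return rec.fail("filtered", "murcko_empty")
        mol = standardize_structure(mol)
    rec.mol = mol
    rec.identity_key = identity_key(mol)
    return rec


def prepare_records(
    records: Iterable[MoleculeRecord],
    cfg: Optional[FilterConfig] = None,
    mode: str = "molecules",
    store: Optional[KeyStore] = None,
) -> Iterator[MoleculeRecord]:
    """Standardize, filter and deduplicate a record stream.

    ``mode="molecules"`` applies sugar removal and the physicochemical
    filters; ``mode="fragments"`` instead extracts Murcko scaffolds. Every
    input record reappears exactly once with a definite status.
    """
    if mode not in ("molecules", "fragments"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = cfg or FilterConfig()

    def staged():
        for rec in records:
            if rec.status != "passed":
                yield rec
                continue
            yield run_with_timeout(
                lambda r: _standardize_record(r, cfg, mode), rec, cfg.timeout_seconds
            )

    yield from deduplicate(staged(), store)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_sdf(records: Iterable[MoleculeRecord], path: str | Path) -> int:
    """Write passed records to an SDF; returns the number written."""
    writer = Chem.SDWriter(str(path))
    n = 0
    for rec in records:
        if rec.status != "passed":
            continue
        mol = Chem.Mol(rec.mol)
        mol.SetProp("_Name", rec.record_id)
        mol.SetProp("identity_key", rec.identity_key or "")
        writer.write(mol)
        n += 1
    writer.close()
    return n


def write_log_tsv(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\tstatus\tremoval_reason\tidentity_key\n")
        for rec in records:
            fh.write(
                f"{rec.record_id}\t{rec.status}\t{rec.removal_reason or ''}"
                f"\t{rec.identity_key or ''}\n"
            )
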