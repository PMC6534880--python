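"""Molecule-set evaluation: validity / desired / uniqueness rates, Tanimoto
internal diversity, substructure statistics, 19D physicochemical
descriptors, 2D chemical-space projections, scaffold-space k-means
comparison, and candidate ranking.

Internal diversity of a set A is the average Tanimoto distance over ALL
ordered pairs of A x A, self-pairs included, divided by |A|^2 — so its
upper bound is (|A|-1)/|A|, not 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from smilesrl.qsar import Fingerprint, PredictorModel, compute_ecfp6, fingerprint_matrix
from smilesrl.vocab import canonical_smiles

SCAFFOLD_MODES = ("full", "murcko", "topological")

_FURAN = Chem.MolFromSmarts("c1ccoc1")
_BENZENE = Chem.MolFromSmarts("c1ccccc1")


def tanimoto_similarity(ma: Fingerprint, mb: Fingerprint) -> float:
    """|ma & mb| / |ma | mb|; two empty fingerprints give 0 by convention."""
    union = len(ma | mb)
    if union == 0:
        return 0.0
    return len(ma & mb) / union


def tanimoto_distance(ma: Fingerprint, mb: Fingerprint) -> float:
    return 1.0 - tanimoto_similarity(ma, mb)


def internal_diversity(smiles_list: list[str],
                       fps: list[Fingerprint] | None = None) -> float:
    """I(A) = (1/|A|^2) * sum over all ordered pairs (self-pairs included)
    of the Tanimoto distance."""
    if fps is None:
        if not smiles_list:
            raise ValueError("empty molecule set")
        fps = [compute_ecfp6(s) for s in smiles_list]
    if not fps:
        raise ValueError("empty molecule set")
    n = len(fps)
    X = fingerprint_matrix(fps)
    counts = X.sum(axis=1)
    inter = X @ X.T
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return float((1.0 - sim).sum() / (n * n))


@dataclass
class EvaluationReport:
    """Batch-level metrics; percentages are over the full batch size."""

    n: int
    valid_pct: float
    desired_pct: float
    unique_pct: float
    unique_desired_pct: float       # unique among desired, as % of batch
    unique_of_desired_pct: float    # unique desired / desired count
    diversity: float                # I(A) on the unique desired subset
    substructure_pct: dict[str, float] | None = None

    def to_tsv(self) -> str:
        rows = [
            ("n", self.n),
            ("valid_pct", self.valid_pct),
            ("desired_pct", self.desired_pct),
            ("unique_pct", self.unique_pct),
            ("unique_desired_pct", self.unique_desired_pct),
            ("unique_of_desired_pct", self.unique_of_desired_pct),
            ("diversity", self.diversity),
        ]
        if self.substructure_pct:
            rows += [(f"{k}_pct", v) for k, v in self.substructure_pct.items()]
        return "metric\tvalue\n" + "\n".join(
            f"{k}\t{v:.4f}" if isinstance(v, float) else f"{k}\t{v}"
            for k, v in rows) + "\n"


def batch_report(smiles_list: list[str], predictor: PredictorModel,
                 desired_threshold: float = 0.5,
                 with_substructures: bool = False) -> EvaluationReport:
    """Compute validity / desired / uniqueness percentages and the internal
    diversity of the unique desired subset of a generated batch."""
    n = len(smiles_list)
    if n == 0:
        raise ValueError("empty batch")
    canon = [canonical_smiles(s) for s in smiles_list]
    valid = [c is not None for c in canon]
    q = np.zeros(n)
    valid_idx = [i for i, ok in enumerate(valid) if ok]
    if valid_idx:
        fps = {i: compute_ecfp6(canon[i]) for i in valid_idx}
        qvals = predictor.predict_q([fps[i] for i in valid_idx])
        for j, i in enumerate(valid_idx):
            q[i] = qvals[j]
    desired = [valid[i] and q[i] > desired_threshold for i in range(n)]

    unique_keys = {canon[i] if valid[i] else f"\x00{smiles_list[i]}"
                   for i in range(n)}
    desired_unique: dict[str, int] = {}
    for i in range(n):
        if desired[i] and canon[i] not in desired_unique:
            desired_unique[canon[i]] = i

    n_desired = sum(desired)
    diversity = 0.0
    if desired_unique:
        diversity = internal_diversity(
            list(desired_unique.keys()),
            fps=[fps[i] for i in desired_unique.values()])
    sub = None
    if with_substructures and valid_idx:
        sub = substructure_stats([canon[i] for i in valid_idx])
    return EvaluationReport(
        n=n,
        valid_pct=100.0 * sum(valid) / n,
        desired_pct=100.0 * n_desired / n,
        unique_pct=100.0 * len(unique_keys) / n,
        unique_desired_pct=100.0 * len(desired_unique) / n,
        unique_of_desired_pct=(100.0 * len(desired_unique) / n_desired
                               if n_desired else 0.0),
        diversity=diversity,
        substructure_pct=sub,
    )


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return mol


def has_fused_ring(mol: Chem.Mol) -> bool:
    """Two or more SSSR rings sharing at least one bond (spiro systems,
    which share only an atom, do not count)."""
    bond_rings = [frozenset(r) for r in mol.GetRingInfo().BondRings()]
    for i in range(len(bond_rings)):
        for j in range(i + 1, len(bond_rings)):
            if bond_rings[i] & bond_rings[j]:
                return True
    return False


def substructure_flags(smiles: str) -> dict[str, bool]:
    mol = _mol(smiles)
    return {
        "fused_ring": has_fused_ring(mol),
        "furan_ring": mol.HasSubstructMatch(_FURAN),
        "benzene_ring": mol.HasSubstructMatch(_BENZENE),
    }


def substructure_stats(smiles_list: list[str]) -> dict[str, float]:
    """Percentages of molecules containing fused rings, furan rings and
    benzene rings."""
    if not smiles_list:
        return {"fused_ring": 0.0, "furan_ring": 0.0, "benzene_ring": 0.0}
    counts = {"fused_ring": 0, "furan_ring": 0, "benzene_ring": 0}
    for s in smiles_list:
        for k, v in substructure_flags(s).items():
            counts[k] += bool(v)
    n = len(smiles_list)
    return {k: 100.0 * v / n for k, v in counts.items()}


PHYSCHEM_NAMES = (
    "logp", "mw", "hbd", "hba", "rotatable_bonds", "aliphatic_rings",
    "aromatic_rings", "heterocycles", "tpsa", "molar_refractivity",
    "fraction_csp3", "amide_bonds", "bridgehead_atoms", "heteroatoms",
    "heavy_atoms", "spiro_atoms", "rings", "saturated_rings",
    "valence_electrons",
)


def physchem(smiles: str) -> dict[str, float]:
    """The 19 physicochemical descriptors used for chemical-space analysis."""
    mol = _mol(smiles)
    return {
        "logp": Crippen.MolLogP(mol),
        "mw": Descriptors.MolWt(mol),
        "hbd": rdMolDescriptors.CalcNumHBD(mol),
        "hba": rdMolDescriptors.CalcNumHBA(mol),
        "rotatable_bonds": rdMolDescriptors.CalcNumRotatableBonds(mol),
        "aliphatic_rings": rdMolDescriptors.CalcNumAliphaticRings(mol),
        "aromatic_rings": rdMolDescriptors.CalcNumAromaticRings(mol),
        "heterocycles": rdMolDescriptors.CalcNumHeterocycles(mol),
        "tpsa": rdMolDescriptors.CalcTPSA(mol),
        "molar_refractivity": Crippen.MolMR(mol),
        "fraction_csp3": rdMolDescriptors.CalcFractionCSP3(mol),
        "amide_bonds": rdMolDescriptors.CalcNumAmideBonds(mol),
        "bridgehead_atoms": rdMolDescriptors.CalcNumBridgeheadAtoms(mol),
        "heteroatoms": rdMolDescriptors.CalcNumHeteroatoms(mol),
        "heavy_atoms": mol.GetNumHeavyAtoms(),
        "spiro_atoms": rdMolDescriptors.CalcNumSpiroAtoms(mol),
        "rings": rdMolDescriptors.CalcNumRings(mol),
        "saturated_rings": rdMolDescriptors.CalcNumSaturatedRings(mol),
        "valence_electrons": Descriptors.NumValenceElectrons(mol),
    }


def physchem_matrix(smiles_list: list[str]) -> np.ndarray:
    return np.array([[physchem(s)[k] for k in PHYSCHEM_NAMES]
                     for s in smiles_list])


def project_space(vectors: np.ndarray, method: str = "PCA",
                  seed: int = 0) -> np.ndarray:
    """2D embedding of descriptor vectors for chemical-space plots."""
    X = np.asarray(vectors, dtype=np.float64)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if method.upper() == "PCA":
        if X.shape[1] < 2:
            raise ValueError("need at least 2 input dimensions")
        return PCA(n_components=2, random_state=seed).fit_transform(X)
    if method.upper() == "TSNE":
        perplexity = min(30.0, (X.shape[0] - 1) / 3.0)
        return TSNE(n_components=2, random_state=seed,
                    perplexity=perplexity, init="pca").fit_transform(X)
    raise ValueError(f"unknown projection method {method!r}")


def _scaffold_smiles(smiles: str, mode: str) -> str:
    if mode == "full":
        return smiles
    mol = _mol(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if mode == "topological":
        try:
            scaffold = MurckoScaffold.MakeScaffoldGeneric(scaffold)
        except Exception:
            pass  # odd valences in generic scaffolds; fall back to Murcko
    return Chem.MolToSmiles(scaffold)


def murcko_scaffold(smiles: str, topological: bool = False) -> str:
    """Murcko scaffold (ring systems + linkers) of a molecule; the
    topological variant abstracts atom types and bond orders."""
    return _scaffold_smiles(smiles, "topological" if topological else "murcko")


@dataclass
class ClusterOccupancy:
    mode: str
    k: int
    reference_counts: np.ndarray
    query_counts: np.ndarray

    @property
    def coverage(self) -> float:
        """Fraction of reference-occupied clusters also occupied by the query."""
        ref_occ = self.reference_counts > 0
        if not ref_occ.any():
            return 0.0
        return float((self.query_counts[ref_occ] > 0).sum() / ref_occ.sum())

    def to_tsv(self) -> str:
        lines = ["cluster\treference\tquery"]
        for i in range(self.k):
            lines.append(f"{i}\t{self.reference_counts[i]}\t{self.query_counts[i]}")
        return "\n".join(lines) + "\n"


def cluster_compare(reference: list[str], query: list[str], k: int = 20,
                    mode: str = "full", seed: int = 0) -> ClusterOccupancy:
    """k-means on pooled ECFP6 fingerprints of the chosen scaffold mode
    (full / murcko / topological); per-cluster occupancy of each set."""
    if mode not in SCAFFOLD_MODES:
        raise ValueError(f"mode must be one of {SCAFFOLD_MODES}")
    n_total = len(reference) + len(query)
    if k > n_total:
        raise ValueError("k exceeds the pooled set size")
    fps = [compute_ecfp6(_scaffold_smiles(s, mode))
           for s in list(reference) + list(query)]
    X = fingerprint_matrix(fps)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    ref_counts = np.bincount(labels[:len(reference)], minlength=k)
    qry_counts = np.bincount(labels[len(reference):], minlength=k)
    return ClusterOccupancy(mode=mode, k=k, reference_counts=ref_counts,
                            query_counts=qry_counts)


def rank_candidates(smiles_list: list[str], predictor: PredictorModel,
                    reference: list[str], top_n: int | None = None):
    """Annotate each molecule with Q and its minimum Tanimoto distance to
    the reference set; sort by Q descending, ties broken by larger distance
    (novelty first).  Returns a list of (smiles, q, min_distance)."""
    if not reference:
        raise ValueError("reference set is empty")
    ref_fps = [compute_ecfp6(s) for s in reference]
    rows = []
    for s in smiles_list:
        fp = compute_ecfp6(s)
        q = float(predictor.predict_q([fp])[0])
        dist = min(tanimoto_distance(fp, rf) for rf in ref_fps)
        rows.append((s, q, dist))
    rows.sort(key=lambda r: (-r[1], -r[2]))
    return rows if top_n is None else rows[:top_n]
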