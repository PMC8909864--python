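"""Generated-library evaluation: validity, uniqueness, novelty, descriptors.

The three library-quality fractions form a chain with distinct denominators:

* validity   = n_valid  / n_sampled  (string parses and sanitizes)
* uniqueness = n_unique / n_valid    (distinct canonical structures)
* novelty    = n_novel  / n_unique   (max MACCS-Tanimoto similarity to the
  reference/training set strictly below the threshold, default 0.85)

so n_novel <= n_unique <= n_valid <= n_sampled always holds.  Descriptor
profiling covers molecular weight, TPSA, Crippen molar refractivity (SMR)
and SlogP, the Ertl–Schuffenhauer synthetic-accessibility score and QED
druglikeness, with a t-SNE embedding for chemical-space comparison of
generated versus training molecules.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import Crippen, Descriptors, MACCSkeys, QED

RDLogger.DisableLog("rdApp.*")


def _sascorer():
    from rdkit.Chem import RDConfig

    sa_dir = os.path.join(RDConfig.RDContribDir, "SA_Score")
    if sa_dir not in sys.path:
        sys.path.append(sa_dir)
    import sascorer

    return sascorer


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class NoveltyConfig:
    """MACCS/Tanimoto novelty rule: novel iff max similarity < threshold."""

    threshold: float = 0.85

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise EvaluationError("threshold must be in (0, 1]")


@dataclass(frozen=True)
class LibraryMetrics:
    n_sampled: int
    n_valid: int
    n_unique: int
    n_novel: int

    @property
    def validity(self) -> float:
        return self.n_valid / self.n_sampled

    @property
    def uniqueness(self) -> float:
        return self.n_unique / self.n_valid if self.n_valid else 0.0

    @property
    def novelty(self) -> float:
        return self.n_novel / self.n_unique if self.n_unique else 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(validity=self.validity, uniqueness=self.uniqueness, novelty=self.novelty)
        return d


def parse_valid(strings: list[str]) -> list[Chem.Mol]:
    """Molecules for the strings that parse and sanitize, in input order."""
    out = []
    for s in strings:
        mol = Chem.MolFromSmiles(s)
        if mol is not None:
            out.append(mol)
    return out


def compute_validity(strings: list[str]) -> tuple[int, float]:
    if not strings:
        raise EvaluationError("empty input")
    n_valid = len(parse_valid(strings))
    return n_valid, n_valid / len(strings)


def compute_uniqueness(
    valid_strings: list[str], by_structure: bool = True
) -> tuple[int, float]:
    """Distinct count among valid strings.

    Default deduplication is by canonical structure (``CCO`` and ``OCC``
    are one molecule); ``by_structure=False`` switches to raw-string
    deduplication.
    """
    if not valid_strings:
        raise EvaluationError("empty input")
    if by_structure:
        keys = {Chem.MolToSmiles(m) for m in parse_valid(valid_strings)}
    else:
        keys = set(valid_strings)
    return len(keys), len(keys) / len(valid_strings)


def maccs_fingerprints(mols: list[Chem.Mol]):
    return [MACCSkeys.GenMACCSKeys(m) for m in mols]


def compute_novelty(
    unique_smiles: list[str],
    training_set: list[str],
    config: NoveltyConfig = NoveltyConfig(),
) -> tuple[int, float]:
    """Novel iff the maximum Tanimoto similarity of MACCS keys against the
    reference set is strictly below the threshold."""
    if not unique_smiles:
        raise EvaluationError("empty unique set")
    ref_mols = parse_valid(training_set)
    if not ref_mols:
        import warnings

        warnings.warn("empty reference set: every molecule counts as novel", stacklevel=2)
        return len(unique_smiles), 1.0
    ref_fps = maccs_fingerprints(ref_mols)
    n_novel = 0
    for s in unique_smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise EvaluationError(f"invalid SMILES in unique set: {s!r}")
        fp = MACCSkeys.GenMACCSKeys(mol)
        sims = DataStructs.BulkTanimotoSimilarity(fp, ref_fps)
        if max(sims) < config.threshold:
            n_novel += 1
    return n_novel, n_novel / len(unique_smiles)


def evaluate_library(
    sampled: list[str],
    training_set: list[str] | None = None,
    novelty_config: NoveltyConfig = NoveltyConfig(),
    by_structure: bool = True,
) -> LibraryMetrics:
    """Full validity -> uniqueness -> novelty chain for one sampled set."""
    if not sampled:
        raise EvaluationError("empty sample")
    mols = parse_valid(sampled)
    n_valid = len(mols)
    if n_valid == 0:
        return LibraryMetrics(len(sampled), 0, 0, 0)
    if by_structure:
        unique = sorted({Chem.MolToSmiles(m) for m in mols})
    else:
        unique = sorted({Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in set(sampled)
                         if Chem.MolFromSmiles(s) is not None})
    if training_set is None:
        n_novel = 0
    else:
        n_novel, _ = compute_novelty(unique, training_set, novelty_config)
    return LibraryMetrics(len(sampled), n_valid, len(unique), n_novel)


_DESCRIPTOR_COLS = ["MW", "TPSA", "SMR", "SlogP", "SA", "QED"]


def compute_descriptors(smiles: list[str]) -> pd.DataFrame:
    """Per-molecule descriptor table (MW, TPSA, SMR, SlogP, SA, QED).

    A molecule whose descriptor computation fails keeps its row with NaN
    values and ``ok=False`` rather than being dropped.
    """
    sascorer = _sascorer()
    rows = []
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        row: dict = {"smiles": s, "ok": False}
        if mol is not None:
            try:
                row.update(
                    MW=Descriptors.MolWt(mol),
                    TPSA=Descriptors.TPSA(mol),
                    SMR=Crippen.MolMR(mol),
                    SlogP=Crippen.MolLogP(mol),
                    SA=sascorer.calculateScore(mol),
                    QED=QED.qed(mol),
                    ok=True,
                )
            except Exception:
                pass
        rows.append(row)
    return pd.DataFrame(rows, columns=["smiles", "ok", *_DESCRIPTOR_COLS])


def summarize_descriptors(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD per descriptor column over rows with ok=True."""
    good = table[table["ok"]]
    return pd.DataFrame({"mean": good[_DESCRIPTOR_COLS].mean(),
                         "sd": good[_DESCRIPTOR_COLS].std(ddof=1)})


def embed_2d(
    features: np.ndarray | pd.DataFrame,
    seed: int = 0,
    perplexity: float = 30.0,
) -> np.ndarray:
    """Standardize features and embed to 2-D with t-SNE (seeded).

    Perplexity is clamped below (N-1)/3 so small inputs remain valid.
    """
    from sklearn.manifold import TSNE
    from sklearn.preprocessing import StandardScaler

    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 5:
        raise EvaluationError("need a 2-D feature table with at least 5 rows")
    if not np.isfinite(X).all():
        bad = sorted(set(np.argwhere(~np.isfinite(X))[:, 0].tolist()))
        raise EvaluationError(f"non-finite features in rows {bad}")
    perp = float(min(perplexity, max(2.0, (X.shape[0] - 1) / 3)))
    Xs = StandardScaler().fit_transform(X)
    tsne = TSNE(n_components=2, perplexity=perp, random_state=seed, init="pca")
    return tsne.fit_transform(Xs)


# -- plotting -----------------------------------------------------------------


def plot_descriptor_histograms(table: pd.DataFrame, out: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    good = table[table["ok"]]
    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    for ax, col in zip(axes.ravel(), _DESCRIPTOR_COLS):
        ax.hist(good[col].dropna(), bins=30)
        ax.set_title(col)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def plot_embedding(
    coords: np.ndarray, labels: list[str], out: str | Path
) -> None:
    """Scatter of 2-D coordinates coloured by group label (e.g. training vs
    generated, or per attachment position)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = np.asarray(coords)
    fig, ax = plt.subplots(figsize=(7, 6))
    for group in dict.fromkeys(labels):
        idx = [i for i, g in enumerate(labels) if g == group]
        ax.scatter(coords[idx, 0], coords[idx, 1], s=8, alpha=0.6, label=str(group))
    ax.legend(markerscale=2, fontsize=8)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
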