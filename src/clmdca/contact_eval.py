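"""Contact ranking and top-L/k precision evaluation.

True contacts are residue pairs whose representative atoms (C-beta, or
C-alpha for glycine) lie strictly closer than 8 angstroms.  Predictions are
ranked by coupling strength after discarding short-range pairs below a
sequence-separation threshold; the two conventional bands are |i-j| >= 6
and |i-j| > 23.  Precision at top L/k is the fraction of the k
highest-ranked predictions that are true, with k as denominator even when
the protein has fewer than k true contacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform


@dataclass
class ContactSet:
    """Residue-pair contacts, either ranked predictions or truth annotations.

    ``entries`` holds 0-based ``(i, j, score)`` triples with i < j; predicted
    sets are sorted by descending score with a lexicographic (i, j) tie-break.
    """

    entries: list
    length: int
    kind: str = "predicted"

    def __post_init__(self):
        seen = set()
        for i, j, _ in self.entries:
            if not 0 <= i < j < self.length:
                raise ValueError(f"contact ({i}, {j}) out of range")
            if (i, j) in seen:
                raise ValueError(f"duplicate contact ({i}, {j})")
            seen.add((i, j))
        if self.kind == "predicted":
            self.entries = sorted(self.entries, key=lambda t: (-t[2], t[0], t[1]))

    def pairs(self) -> set:
        return {(i, j) for i, j, _ in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


def true_contacts(coords, residue_names=None, cutoff: float = 8.0, length=None) -> ContactSet:
    """Truth contacts from per-residue representative coordinates (angstrom).

    A pair is in contact when its Euclidean distance is strictly below
    ``cutoff`` (default 8 angstrom).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("empty coordinate set")
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coordinates must have shape (n, 3)")
    n = coords.shape[0]
    if residue_names is not None and len(residue_names) != n:
        raise ValueError("residue_names length does not match coordinates")
    dist = squareform(pdist(coords))
    entries = [
        (i, j, float(dist[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if dist[i, j] < cutoff
    ]
    return ContactSet(entries, length=length or n, kind="truth")


def representative_coordinates(pdb_path, chain: str | None = None, model_index: int = 0):
    """Representative-atom coordinates from a PDB file (first model).

    Returns ``(coords, names, residue_ids)`` for residues that have a C-beta
    atom (C-alpha for glycine).  Non-glycine residues missing C-beta fall
    back to C-alpha with a warning; residues with neither are skipped.
    """
    from Bio.PDB import PDBParser, is_aa

    structure = PDBParser(QUIET=True).get_structure("s", str(pdb_path))
    mdl = list(structure)[model_index]
    chains = [c for c in mdl if chain is None or c.id == chain]
    if not chains:
        raise ValueError(f"chain {chain!r} not found in {pdb_path}")
    coords, names, resids = [], [], []
    for ch in chains[:1]:
        for res in ch:
            if not is_aa(res, standard=False):
                continue
            name = res.get_resname()
            atom = "CA" if name == "GLY" else "CB"
            if atom not in res:
                if atom == "CB" and "CA" in res:
                    warnings.warn(
                        f"residue {name} {res.id[1]} lacks CB; using CA"
                    )
                    atom = "CA"
                else:
                    continue
            coords.append(res[atom].coord)
            names.append(name)
            resids.append(res.id[1])
    if not coords:
        raise ValueError(f"no usable residues in {pdb_path}")
    return np.asarray(coords, dtype=float), names, resids


def rank_contacts(scores, min_separation: int = 6) -> ContactSet:
    """Ranked predicted contacts from a symmetric coupling-score matrix.

    Keeps all pairs with ``j - i >= min_separation``, sorted by descending
    score with a deterministic lexicographic tie-break.
    """
    scores = np.asarray(scores)
    if scores.ndim != 2 or scores.shape[0] != scores.shape[1]:
        raise ValueError("scores must be a square matrix")
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    length = scores.shape[0]
    entries = [
        (i, j, float(scores[i, j]))
        for i in range(length)
        for j in range(i + min_separation, length)
    ]
    return ContactSet(entries, length=length, kind="predicted")


def precision_topk(predicted: ContactSet, truth: ContactSet, top="L/5") -> float:
    """Precision of the top-k predictions against the truth set.

    ``top`` is either an explicit integer k (capped at the number of
    available predictions) or one of the strings "L/10", "L/5", "L/2", "L",
    interpreted as k = floor(L / denominator).  The evaluated k is the
    denominator of the returned fraction.
    """
    if predicted.length != truth.length:
        raise ValueError("predicted and truth sets have different lengths")
    if isinstance(top, str):
        label = top.replace(" ", "")
        if label == "L":
            k = predicted.length
        elif label.startswith("L/"):
            k = predicted.length // int(label[2:])
        else:
            raise ValueError(f"unknown top-k specification {top!r}")
    else:
        k = int(top)
    k = min(k, len(predicted.entries))
    if k <= 0:
        raise ValueError("top-k evaluation requires k >= 1")
    true_pairs = truth.pairs()
    hits = sum(1 for i, j, _ in predicted.entries[:k] if (i, j) in true_pairs)
    return hits / k
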