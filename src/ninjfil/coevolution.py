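"""Intra- vs inter-protomer classification of evolutionary-coupling pairs.

Evolutionary couplings (ECs) score the co-variation of two residue positions
across a sequence alignment; strong couplings normally mark intramolecular
contacts. On a polymer, however, a coupling can instead reflect a contact
*between* subunits. Given a filament assembly and an EC pair table, the
functions here measure for every pair the CA-CA distance within one subunit
(d_intra) and the minimum CA-CA distance across distinct subunits
(d_inter_min) and label each pair:

* ``excluded``       -- min(d_intra, d_inter_min) above the distance cutoff
                        (default 12 A between CA atoms);
* ``inter_dominant`` -- d_inter_min strictly shorter than d_intra;
* ``intra_dominant`` -- otherwise (ties count as intra: "shorter" is strict).

For NINJ1 the reference analysis takes the top 100 pairs with score > 0.5
over residues 33-144 and finds nine inter-dominant pairs, the
highest-scoring of which (G95-F127) links helices a3 and a4 of adjacent
subunits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assembly import AssemblyModel
from .errors import InvalidModelError

logger = logging.getLogger(__name__)

LABEL_INTRA = "intra_dominant"
LABEL_INTER = "inter_dominant"
LABEL_EXCLUDED = "excluded"


@dataclass(frozen=True)
class CouplingPair:
    """An EC residue pair (author numbering) with its coupling score."""

    res_i: int
    res_j: int
    score: float

    def __post_init__(self):
        if self.res_i == self.res_j:
            raise InvalidModelError(f"self-coupling ({self.res_i}) is not a pair")


@dataclass(frozen=True)
class PairContactClass:
    """A classified EC pair with its intra- and inter-subunit CA distances."""

    pair: CouplingPair
    d_intra: float
    d_inter_min: float | None
    label: str


@dataclass
class ClassificationResult:
    pairs: list
    summary: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "res_i": [p.pair.res_i for p in self.pairs],
                "res_j": [p.pair.res_j for p in self.pairs],
                "score": [p.pair.score for p in self.pairs],
                "d_intra": [p.d_intra for p in self.pairs],
                "d_inter_min": [p.d_inter_min for p in self.pairs],
                "label": [p.label for p in self.pairs],
            }
        )


def _ca_lookup(assembly: AssemblyModel) -> dict:
    """Map residue id -> (n_subunits, 3) CA coordinates stacked over subunits."""
    out: dict[int, np.ndarray] = {}
    per_subunit = []
    for s in range(assembly.n_subunits):
        sl = assembly._slice(s)
        sub = assembly.atoms[sl]
        coords = assembly.coords[sl]
        mask = sub.atom_name == "CA"
        per_subunit.append(dict(zip(sub.res_id[mask].tolist(), coords[mask])))
    for res in per_subunit[0]:
        out[res] = np.stack([d[res] for d in per_subunit if res in d])
    return out


def pair_distances(
    assembly: AssemblyModel, pair: CouplingPair, rigid_tol: float | None = 1e-6
) -> tuple[float, float | None]:
    """CA-CA distances of a pair: within one subunit and the cross-subunit minimum.

    d_intra is measured on the reference subunit; subunits of a generated
    assembly are rigid copies, so it is subunit-independent, which is
    asserted to ``rigid_tol`` (pass None to skip for deposited models whose
    chains are only approximately identical). d_inter_min minimises over
    all ordered subunit pairs p != q; for a single-subunit assembly it is
    None.
    """
    lut = _ca_lookup(assembly)
    for res in (pair.res_i, pair.res_j):
        if res not in lut or len(lut[res]) != assembly.n_subunits:
            raise InvalidModelError(f"residue {res} lacks a CA atom in some subunit")
    ci, cj = lut[pair.res_i], lut[pair.res_j]  # (S, 3) each
    d_matrix = np.linalg.norm(ci[:, None, :] - cj[None, :, :], axis=-1)  # (S, S)
    d_intra = float(d_matrix[0, 0])
    if assembly.n_subunits == 1:
        return d_intra, None
    intra_all = np.diagonal(d_matrix)
    if rigid_tol is not None and np.abs(intra_all - d_intra).max() > rigid_tol:
        raise InvalidModelError(
            f"intra-subunit distance of pair ({pair.res_i},{pair.res_j}) varies "
            "across subunits; subunits are not rigid copies"
        )
    off = d_matrix[~np.eye(len(d_matrix), dtype=bool)]
    return d_intra, float(off.min())


def classify_pair(
    d_intra: float, d_inter_min: float | None, max_dist: float
) -> str:
    """Apply the labelling rule to one pair's distances."""
    d_min = d_intra if d_inter_min is None else min(d_intra, d_inter_min)
    if d_min > max_dist:
        return LABEL_EXCLUDED
    if d_inter_min is not None and d_inter_min < d_intra:
        return LABEL_INTER
    return LABEL_INTRA


def classify_pairs(
    assembly: AssemblyModel,
    pairs: list,
    top_n: int = 100,
    score_min: float = 0.5,
    max_dist: float = 12.0,
    rigid_tol: float | None = 1e-6,
) -> ClassificationResult:
    """Classify the strongest EC pairs on an assembly.

    Keeps the ``top_n`` pairs with score > ``score_min`` (descending score,
    stable order), measures their distances and labels them. Returns the
    classified pairs plus summary counts.
    """
    kept = sorted(
        (p for p in pairs if p.score > score_min),
        key=lambda p: -p.score,
    )[:top_n]
    classified = []
    for pair in kept:
        d_intra, d_inter = pair_distances(assembly, pair, rigid_tol=rigid_tol)
        label = classify_pair(d_intra, d_inter, max_dist)
        classified.append(
            PairContactClass(pair=pair, d_intra=d_intra, d_inter_min=d_inter, label=label)
        )
    summary = {
        "n_analysed": len(classified),
        "n_inter": sum(p.label == LABEL_INTER for p in classified),
        "n_intra": sum(p.label == LABEL_INTRA for p in classified),
        "n_excluded": sum(p.label == LABEL_EXCLUDED for p in classified),
    }
    return ClassificationResult(pairs=classified, summary=summary)


def read_coupling_table(path, offset: int = 0) -> list:
    """Read an EC pair table (CSV with residue indices i, j and a score).

    Column names are matched case-insensitively against common EC output
    dialects (i/j/score, res_i/res_j, pos_i/pos_j, cn); a headerless
    three-column file is accepted too. Duplicated unordered pairs keep the
    maximum score; malformed rows are skipped and counted. ``offset`` is
    added to both indices to map alignment columns to author numbering.
    """
    df = pd.read_csv(path, comment="#")
    cols = {str(c).strip().lower(): c for c in df.columns}

    def _find(*names):
        for n in names:
            if n in cols:
                return cols[n]
        return None

    col_i = _find("i", "res_i", "pos_i", "resi", "position_i")
    col_j = _find("j", "res_j", "pos_j", "resj", "position_j")
    col_s = _find("score", "cn", "ec_score", "coupling_score", "fn")
    if col_i is None or col_j is None or col_s is None:
        # headerless: first row was consumed as a header; re-read positionally
        df = pd.read_csv(path, header=None, comment="#")
        if df.shape[1] < 3:
            raise InvalidModelError(f"{path}: need at least 3 columns (i, j, score)")
        col_i, col_j, col_s = df.columns[:3]

    raw_n = len(df)
    num = df[[col_i, col_j, col_s]].apply(pd.to_numeric, errors="coerce").dropna()
    num = num[num[col_i] != num[col_j]]
    skipped = raw_n - len(num)
    if skipped:
        logger.warning("%s: skipped %d malformed row(s)", path, skipped)
    if num.empty:
        raise InvalidModelError(f"{path}: no parseable coupling rows")

    best: dict[tuple[int, int], float] = {}
    order: list[tuple[int, int]] = []
    for i, j, s in num.itertuples(index=False):
        key = tuple(sorted((int(i) + offset, int(j) + offset)))
        if key not in best:
            order.append(key)
            best[key] = float(s)
        else:
            best[key] = max(best[key], float(s))
    return [CouplingPair(res_i=k[0], res_j=k[1], score=best[k]) for k in order]


def write_classification(result: ClassificationResult, csv_path, json_path=None) -> None:
    """Write the classified pairs as CSV and (optionally) the summary as JSON."""
    result.to_frame().to_csv(csv_path, index=False)
    if json_path is not None:
        import json

        with open(json_path, "w") as fh:
            json.dump(result.summary, fh, indent=2)
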