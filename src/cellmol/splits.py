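"""Molecule-grouped train/valid/test splits.

All images of one molecule always land in the same set, so evaluation
never sees a structure whose views were trained on.  The scaffold mode
additionally keeps molecules sharing a Bemis-Murcko scaffold together,
probing generalization to new chemotypes.
"""

from __future__ import annotations

import numpy as np

from .records import MoleculeRecord, SplitAssignment

__all__ = ["make_split"]

DEFAULT_FRACTIONS = (0.7, 0.1, 0.2)


def _partition_sizes(n: int, fractions: tuple[float, float, float]) -> list[int]:
    # floor of cumulative targets => sizes sum to n and track fractions
    # (epsilon guards against 0.7 + 0.1 = 0.7999... style float drift)
    bounds = [int(np.floor(sum(fractions[:i + 1]) * n + 1e-9)) for i in range(3)]
    bounds[-1] = n
    sizes = [bounds[0], bounds[1] - bounds[0], bounds[2] - bounds[1]]
    return sizes


def make_split(molecules: list[MoleculeRecord], mode: str = "random_by_molecule",
               fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
               seed: int = 0) -> SplitAssignment:
    """Assign each molecule to train/valid/test.

    random_by_molecule shuffles molecule ids (sorted first, so the result
    is invariant to input order) and partitions by the cumulative
    fractions.  scaffold groups molecules by ``scaffold_key`` and assigns
    whole groups, largest first, to the set with the largest remaining
    deficit relative to its target count.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(molecules) < 3:
        raise ValueError("need at least as many molecules as sets")
    if mode not in ("random_by_molecule", "scaffold"):
        raise ValueError(f"unknown split mode: {mode}")

    rng = np.random.default_rng(seed)
    ids = sorted(m.molecule_id for m in molecules)
    n = len(ids)
    sets = SplitAssignment.SETS

    if mode == "random_by_molecule":
        order = rng.permutation(n)
        sizes = _partition_sizes(n, fractions)
        assignment = {}
        start = 0
        for set_name, size in zip(sets, sizes):
            for idx in order[start:start + size]:
                assignment[ids[idx]] = set_name
            start += size
        return SplitAssignment(assignment, mode=mode)

    # scaffold mode
    key_of = {m.molecule_id: m.scaffold_key for m in molecules}
    groups: dict[str, list[str]] = {}
    for mol_id in ids:
        groups.setdefault(key_of[mol_id], []).append(mol_id)
    # shuffle group order by seed, then process largest groups first so the
    # greedy fill can still balance with the small groups that remain
    keys = sorted(groups)
    rng.shuffle(keys)
    keys.sort(key=lambda k: -len(groups[k]))
    targets = [f * n for f in fractions]
    filled = [0, 0, 0]
    assignment = {}
    for key in keys:
        deficits = [targets[i] - filled[i] for i in range(3)]
        dest = int(np.argmax(deficits))
        for mol_id in groups[key]:
            assignment[mol_id] = sets[dest]
        filled[dest] += len(groups[key])
    return SplitAssignment(assignment, mode=mode)
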