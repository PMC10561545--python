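"""Synthetic molecule families with planted similarity structure.

:func:`generate_family` emulates the structure of real analog series — a
shared scaffold (a quinazoline kinase-inhibitor core or a peptide-like
chain) decorated with enumerated substituents, plus structurally unrelated
decoys — so the whole pipeline can be exercised without any download.
Ground-truth family labels travel with the ids (``famX_...`` / ``decoy_...``).

:func:`worked_example_set` packages a handful of literal drug structures
whose pairings span both ends of the amcd scale: l-tyrosine / l-DOPA are a
classic matched pair (one added hydroxyl), while tetrabenazine / hydrocodone
share most of their atoms but are related only by an exotic double
cyclization — an alchemical transmutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import MoleculeSet, standardize_set

__all__ = ["FixtureSpec", "generate_family", "worked_example_set", "WORKED_EXAMPLES"]


@dataclass(frozen=True)
class FixtureSpec:
    n_scaffolds: int = 2
    substituents_per_scaffold: int = 5
    n_decoys: int = 4
    seed: int = 0


# Scaffold templates: "{R}" is the substituent attachment point.
# fam0: 4-anilinoquinazoline (EGFR-inhibitor-like core)
# fam1: phenylpiperazine amide
# fam2: indole-3-acetamide
# fam3: benzodiazepine-like benzamide chain
_SCAFFOLDS = [
    "{R}c1ccc2ncnc(Nc3ccccc3)c2c1",
    "{R}c1ccc(N2CCN(C(C)=O)CC2)cc1",
    "{R}c1ccc2[nH]c(CC(N)=O)cc2c1",
    "{R}c1ccc(C(=O)NCCc2ccccc2)cc1",
]

# written attachment-last so "{R}" prefixing bonds the final atom to the ring
_SUBSTITUENTS = [
    "C", "CC", "CCC", "CC(C)", "O", "CO", "CCO", "N", "CN",
    "F", "Cl", "Br", "FC(F)(F)", "N#C", "CC(C)O", "CCCC",
]

_DECOYS = [
    "OC[C@H]1O[C@@H](O)[C@H](O)[C@@H](O)[C@@H]1O",        # glucose
    "CC(=O)Oc1ccccc1C(=O)O",                               # aspirin
    "CN1CCC[C@H]1c1cccnc1",                                # nicotine
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",                       # salbutamol
    "CCCCCCCCCCCCCCCC(=O)O",                               # palmitic acid
    "C[C@]12CC[C@H]3[C@@H](CCC4=CC(=O)CC[C@]34C)[C@@H]1CCC2=O",  # androstenedione
    "OCCN1CCN(CCCN2c3ccccc3Sc3ccc(Cl)cc32)CC1",            # perphenazine-like
    "Nc1ncnc2[nH]cnc12",                                   # adenine
]


def generate_family(spec: FixtureSpec = FixtureSpec()) -> MoleculeSet:
    """Scaffold families with enumerated substituents plus unrelated decoys.

    Deterministic for a given seed; ids encode the ground-truth family
    (``fam<i>_<j>`` for family members, ``decoy_<j>`` for decoys).
    """
    if spec.n_scaffolds > len(_SCAFFOLDS):
        raise ValueError(f"at most {len(_SCAFFOLDS)} scaffolds available")
    if spec.n_decoys > len(_DECOYS):
        raise ValueError(f"at most {len(_DECOYS)} decoys available")
    rng = np.random.default_rng(spec.seed)
    raw: list[tuple[str, str]] = []
    for s in range(spec.n_scaffolds):
        subs = rng.permutation(len(_SUBSTITUENTS))[: spec.substituents_per_scaffold]
        for j, sub_idx in enumerate(sorted(subs)):
            smi = _SCAFFOLDS[s].format(R=_SUBSTITUENTS[sub_idx])
            raw.append((f"fam{s}_{j}", smi))
    for j in range(spec.n_decoys):
        raw.append((f"decoy_{j}", _DECOYS[j]))
    return standardize_set(raw, name=f"fixture_seed{spec.seed}")


# Literal structures for the worked examples (names -> SMILES).
WORKED_EXAMPLES = {
    "tyrosine": "N[C@@H](Cc1ccc(O)cc1)C(O)=O",
    "levodopa": "N[C@@H](Cc1ccc(O)c(O)c1)C(O)=O",
    "tetrabenazine": "COc1cc2c(cc1OC)[C@@H]1CC(=O)[C@H](CC(C)C)CN1CC2",
    "hydrocodone": "COc1ccc2C[C@@H]3[C@@H]4CCC(=O)[C@@H]5Oc1c2[C@]45CCN3C",
    "afatinib": "CN(C)C/C=C/C(=O)Nc1cc2c(Nc3ccc(F)c(Cl)c3)ncnc2cc1O[C@@H]1CCOC1",
    "osimertinib": "C=CC(=O)Nc1cc(Nc2nccc(-c3cn(C)c4ccccc34)n2)c(OC)cc1N(C)CCN(C)C",
}


def worked_example_set() -> MoleculeSet:
    """Six drugs spanning the feasible-to-alchemical amcd range.

    Tyrosine -> levodopa is a hydroxylation (one added oxygen, low amcd);
    tetrabenazine -> hydrocodone needs a double cyclization (high amcd);
    afatinib / osimertinib are EGFR inhibitors related by combined
    substituent and ring-system changes.
    """
    return standardize_set(list(WORKED_EXAMPLES.items()), name="worked_examples")
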