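"""Pinned drug-like SMILES fixtures for featurization and I/O tests.

The list combines well-known drug and reagent structures with a small
combinatorial set of substituted scaffolds, giving ~200 distinct valid
strings.  The generator in :mod:`htsval.synth` works feature-first, so
chemistry parsing is never on any workflow's critical path — these
strings only exercise the RDKit-facing code.
"""

from __future__ import annotations

from functools import lru_cache

_NAMED = [
    "CC(=O)Oc1ccccc1C(=O)O",            # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",       # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",       # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",               # paracetamol
    "Clc1ccccc1C(=O)Nc1ccccc1",         # anilide
    "OC(=O)c1ccccc1O",                  # salicylic acid
    "NC(=O)c1ccccc1",                   # benzamide
    "c1ccc2c(c1)cc[nH]2",               # indole
    "c1ccc2c(c1)ncc(n2)N",              # aminoquinoxaline
    "CN1CCC[C@H]1c1cccnc1",             # nicotine
    "OCC(O)CO",                         # glycerol
    "CC(N)Cc1ccccc1",                   # amphetamine
    "NCCc1ccc(O)c(O)c1",                # dopamine
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",       # citric acid
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",    # salbutamol
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",     # naproxen
    "CN(C)CCOC(c1ccccc1)c1ccccc1",      # diphenhydramine
    "Clc1ccc(cc1)C(c1ccccc1)N1CCN(CC1)CCO",  # hydroxyzine-like
    "O=C1CCCN1C",                       # N-methylpyrrolidone
    "O=C(O)c1cc(O)c(O)c(O)c1",          # gallic acid
    "Nc1ccc(cc1)S(=O)(=O)N",            # sulfanilamide
    "COC(=O)c1ccccc1N",                 # methyl anthranilate
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",       # procainamide
    "CSCCC(N)C(=O)O",                   # methionine
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",      # tryptophan
    "OCC1OC(O)C(O)C(O)C1O",             # glucose
    "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O",   # estradiol
    "CC(C)NCC(O)COc1ccc2ccccc2c1",      # propranolol
    "CC(=O)NCCc1c[nH]c2ccc(OC)cc12",    # melatonin
    "O=c1[nH]c(=O)c2[nH]cnc2[nH]1",     # uric acid-like
    "Nc1ncnc2[nH]cnc12",                # adenine
    "CC1=CC(=O)CC(C)(C)C1",             # isophorone
    "O=C(Nc1ccccc1)Nc1ccccc1",          # diphenylurea
    "CCOC(=O)c1ccccc1",                 # ethyl benzoate
    "COc1cc(C=CC(=O)O)ccc1O",           # ferulic acid
    "CC(C)=CCCC(C)=CC=O",               # citral
    "c1ccc(cc1)c1ccccc1",               # biphenyl
    "C1CCC2(CC1)OCCO2",                 # ketal
    "O=S(=O)(c1ccccc1)N1CCCCC1",        # sulfonylpiperidine
    "CN1CCN(CC1)c1ccccc1",              # phenylpiperazine
]

_SUBSTITUENTS = [
    "C", "CC", "CCC", "CCCC", "CO", "CCO", "CN", "CCN",
    "OC(=O)", "NC(=O)", "O=S(=O)(N)", "FC(F)(F)", "Cl", "Br", "N#C", "COC",
]

_SCAFFOLDS = [
    "c1ccccc1",           # benzene
    "c1ccncc1",           # pyridine
    "c1ccc2ccccc2c1",     # naphthalene
    "C1CCCCC1",           # cyclohexane
    "C1CCNCC1",           # piperidine
    "c1ccsc1",            # thiophene
    "c1ccoc1",            # furan
    "c1cnccn1",           # pyrazine
    "C1CCOC1",            # tetrahydrofuran
    "c1ccc2ncccc2c1",     # quinoline
]


@lru_cache(maxsize=1)
def fixture_smiles() -> tuple[str, ...]:
    """~200 distinct valid SMILES (RDKit-validated at first call)."""
    from rdkit import Chem

    candidates = list(_NAMED)
    for sub in _SUBSTITUENTS:
        for scaf in _SCAFFOLDS:
            candidates.append(sub + scaf)
    seen, out = set(), []
    for smi in candidates:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon not in seen:
            seen.add(canon)
            out.append(smi)
    return tuple(out)
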