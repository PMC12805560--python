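"""Bundled offline dictionary of common trivial names.

Maps lowercased trivial names of molecules that come up in introductory
chemistry teaching to their SMILES notation.  The dictionary is
intentionally small and offline: anything not listed here is treated as a
SMILES string by the input resolver, and users needing exotic compounds
can look the notation up in a chemical database themselves.
"""

from __future__ import annotations

#: lowercase trivial name -> SMILES
TRIVIAL_NAMES: dict[str, str] = {
    # fundamentals
    "hydrogen": "[H][H]",
    "water": "O",
    "ammonia": "N",
    "carbon dioxide": "O=C=O",
    "carbon monoxide": "[C-]#[O+]",
    "hydrogen peroxide": "OO",
    "hydrogen sulfide": "S",
    "ozone": "[O-][O+]=O",
    "nitrogen": "N#N",
    "oxygen": "O=O",
    # alkanes
    "methane": "C",
    "ethane": "CC",
    "propane": "CCC",
    "butane": "CCCC",
    "isobutane": "CC(C)C",
    "pentane": "CCCCC",
    "hexane": "CCCCCC",
    "heptane": "CCCCCCC",
    "octane": "CCCCCCCC",
    "cyclopropane": "C1CC1",
    "cyclobutane": "C1CCC1",
    "cyclopentane": "C1CCCC1",
    "cyclohexane": "C1CCCCC1",
    # alkenes / alkynes
    "ethene": "C=C",
    "ethylene": "C=C",
    "propene": "CC=C",
    "ethyne": "C#C",
    "acetylene": "C#C",
    "butadiene": "C=CC=C",
    "isoprene": "CC(=C)C=C",
    # alcohols and ethers
    "methanol": "CO",
    "ethanol": "CCO",
    "propanol": "CCCO",
    "isopropanol": "CC(O)C",
    "glycerol": "OCC(O)CO",
    "ethylene glycol": "OCCO",
    "dimethyl ether": "COC",
    "diethyl ether": "CCOCC",
    # carbonyls and acids
    "formaldehyde": "C=O",
    "acetaldehyde": "CC=O",
    "acetone": "CC(=O)C",
    "formic acid": "OC=O",
    "acetic acid": "CC(=O)O",
    "oxalic acid": "OC(=O)C(=O)O",
    "lactic acid": "CC(O)C(=O)O",
    "citric acid": "OC(=O)CC(O)(C(=O)O)CC(=O)O",
    "ethyl acetate": "CCOC(=O)C",
    # aromatics
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "phenol": "Oc1ccccc1",
    "styrene": "C=Cc1ccccc1",
    "aniline": "Nc1ccccc1",
    "benzoic acid": "OC(=O)c1ccccc1",
    "naphthalene": "c1ccc2ccccc2c1",
    # nitrogen compounds
    "methylamine": "CN",
    "urea": "NC(=O)N",
    "glycine": "NCC(=O)O",
    "alanine": "CC(N)C(=O)O",
    # sugars and biomolecules
    "glucose": "OCC1OC(O)C(O)C(O)C1O",
    "fructose": "OCC1(O)OCC(O)C(O)C1O",
    "ribose": "OCC1OC(O)C(O)C1O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "vanillin": "COc1cc(C=O)ccc1O",
    "menthol": "CC(C)C1CCC(C)CC1O",
    "limonene": "CC(=C)C1CCC(C)=CC1",
    # halogenated
    "chloroform": "ClC(Cl)Cl",
    "chloromethane": "CCl",
    "tetrachloromethane": "ClC(Cl)(Cl)Cl",
}


def lookup(name: str) -> str | None:
    """Return the SMILES for a trivial name, or ``None`` if unknown.

    Matching is case-insensitive and ignores surrounding whitespace.
    """
    return TRIVIAL_NAMES.get(name.strip().lower())
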