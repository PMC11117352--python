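"""Family taxonomy and deterministic synthetic protein construction.

The three-level taxonomy (superfamily > family > element) follows the scheme
used for teleost LTR retrotransposons: Gypsy contains Gmr, Mag, V-clade,
CsRN1 and Barthez; ERV contains Orthoretrovirinae and Epsilon retrovirus;
BEL-PAO and Copia are their own families.

All protein material here is synthetic: domain cores are fixed consensus
peptides shared across families (domains are conserved), embedded in
family-specific random padding (families diverge outside the cores).  The
same constructions feed the bundled domain profiles, the reference panel and
the synthetic-genome generator, so detection -> annotation -> classification
closes the loop with known ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .profiles import (
    AA_ALPHABET,
    DomainModel,
    build_profile,
    save_models_tsv,
)
from .seq_core import ProteinSequence

FAMILY_TO_SUPERFAMILY: dict[str, str] = {
    "Gmr": "Gypsy",
    "Mag": "Gypsy",
    "V-clade": "Gypsy",
    "CsRN1": "Gypsy",
    "Barthez": "Gypsy",
    "BEL-PAO": "BEL-PAO",
    "Copia": "Copia",
    "Orthoretrovirinae": "ERV",
    "Epsilon retrovirus": "ERV",
}

SUPERFAMILIES = ("Gypsy", "BEL-PAO", "Copia", "ERV")

#: canonical spacing (aa) between the second D and the E of the integrase
#: catalytic triad in Gypsy/Copia/ERV integrases
CANONICAL_DDE_SPACING = 35
#: BEL-PAO integrases show heterogeneous D2->E spacing; the synthetic
#: BEL-PAO core uses 42
BEL_PAO_DDE_SPACING = 42

_DOMAIN_LENGTHS = {"GAG": 80, "POL": 100, "RT": 90, "RH": 60, "ENV": 70, "INT": 120}
_INT_CATALYTIC = (10, 70, 105)  # D1, D2, E columns; D2->E spacing 35
_CONSENSUS_SEED = 20240510

_AA_NO_DE = AA_ALPHABET.replace("D", "").replace("E", "")


def _seed_for(name: str) -> int:
    return zlib.crc32(name.encode()) & 0x7FFFFFFF


def domain_consensus_peptides() -> dict[str, str]:
    """Fixed consensus peptides for the six domain models.

    The INT consensus carries the D..D..E catalytic triad at columns
    (10, 70, 105) — D2->E spacing 35 — and no other D/E residues, so triad
    localization is unambiguous on undecayed synthetic integrases.
    """
    rng = np.random.default_rng(_CONSENSUS_SEED)
    out: dict[str, str] = {}
    for name, length in _DOMAIN_LENGTHS.items():
        if name == "INT":
            residues = list(rng.choice(list(_AA_NO_DE), size=length))
            d1, d2, e = _INT_CATALYTIC
            residues[d1] = "D"
            residues[d2] = "D"
            residues[e] = "E"
            out[name] = "".join(residues)
        else:
            out[name] = "".join(rng.choice(list(AA_ALPHABET), size=length))
    return out


def build_default_models() -> dict[str, DomainModel]:
    """Profile score models for the six domains from the fixed consensi."""
    cons = domain_consensus_peptides()
    models = {}
    for name, pep in cons.items():
        cat = _INT_CATALYTIC if name == "INT" else ()
        models[name] = build_profile(name, pep, catalytic=cat)
    return models


def _int_core(family: str, cons: dict[str, str]) -> str:
    """Family's integrase core; BEL-PAO moves E to D2+42 (non-canonical)."""
    core = cons["INT"]
    if FAMILY_TO_SUPERFAMILY[family] != "BEL-PAO":
        return core
    d1, d2, e = _INT_CATALYTIC
    res = list(core)
    res[e] = "K"
    res[d2 + BEL_PAO_DDE_SPACING] = "E"
    return "".join(res)


def _pad(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA_NO_DE), size=n)) if n > 0 else ""


def _assemble(parts: list[str], pads: list[int], rng: np.random.Generator) -> str:
    """Interleave fixed parts with random pads: pad0 part0 pad1 part1 ..."""
    chunks = []
    for pad_len, part in zip(pads, parts + [""]):
        chunks.append(_pad(rng, pad_len))
        chunks.append(part)
    return "".join(chunks)


def _split(total: int, weights: list[float]) -> list[int]:
    raw = [int(total * w) for w in weights]
    raw[-1] += total - sum(raw)
    return raw


def family_pol_protein(family: str, length_aa: int) -> str:
    """Deterministic pol polyprotein: POL core + RT + RH + INT in family padding.

    Copia places INT before RT/RH (its characteristic domain order); all
    other families use RT-RH-INT.
    """
    cons = domain_consensus_peptides()
    intc = _int_core(family, cons)
    if FAMILY_TO_SUPERFAMILY[family] == "Copia":
        parts = [cons["POL"], intc, cons["RT"], cons["RH"]]
    else:
        parts = [cons["POL"], cons["RT"], cons["RH"], intc]
    fixed = sum(len(p) for p in parts) + 1
    if length_aa < fixed + 4:
        raise ValueError(f"pol length {length_aa} too short for domain cores ({fixed})")
    rng = np.random.default_rng(_seed_for(f"{family}|pol"))
    pads = _split(length_aa - fixed, [0.1, 0.25, 0.25, 0.2, 0.2])
    return "M" + _assemble(parts, pads, rng)


def family_gag_protein(family: str, length_aa: int) -> str:
    cons = domain_consensus_peptides()
    fixed = len(cons["GAG"]) + 1
    if length_aa < fixed + 2:
        raise ValueError(f"gag length {length_aa} too short ({fixed} needed)")
    rng = np.random.default_rng(_seed_for(f"{family}|gag"))
    pads = _split(length_aa - fixed, [0.3, 0.7])
    return "M" + _assemble([cons["GAG"]], pads, rng)


def family_env_protein(family: str, length_aa: int) -> str:
    cons = domain_consensus_peptides()
    fixed = len(cons["ENV"]) + 1
    if length_aa < fixed + 2:
        raise ValueError(f"env length {length_aa} too short ({fixed} needed)")
    rng = np.random.default_rng(_seed_for(f"{family}|env"))
    pads = _split(length_aa - fixed, [0.4, 0.6])
    return "M" + _assemble([cons["ENV"]], pads, rng)


def family_gagpol_protein(family: str, length_aa: int) -> str:
    """Fused gag-pol single-ORF polyprotein (Gmr / Mag layout)."""
    cons = domain_consensus_peptides()
    intc = _int_core(family, cons)
    parts = [cons["GAG"], cons["POL"], cons["RT"], cons["RH"], intc]
    fixed = sum(len(p) for p in parts) + 1
    if length_aa < fixed + 5:
        raise ValueError(f"gag-pol length {length_aa} too short ({fixed} needed)")
    rng = np.random.default_rng(_seed_for(f"{family}|gagpol"))
    pads = _split(length_aa - fixed, [0.1, 0.2, 0.25, 0.15, 0.15, 0.15])
    return "M" + _assemble(parts, pads, rng)


# --- reference panel -------------------------------------------------------

#: representative RT-bearing ORF length (aa) per family, used for the panel
_PANEL_POL_LENGTHS = {
    "Gmr": 1634,  # fused gag-pol
    "Mag": 1365,  # fused gag-pol
    "V-clade": 1119,
    "CsRN1": 1061,
    "Barthez": 1394,
    "BEL-PAO": 1434,
    "Copia": 653,
    "Orthoretrovirinae": 1108,
    "Epsilon retrovirus": 951,
}

BUNDLED_PANEL = "reference_panel.synthetic.fasta"


@dataclass(frozen=True)
class PanelEntry:
    protein: ProteinSequence
    family: str
    superfamily: str


def build_reference_panel() -> list[PanelEntry]:
    """Deterministic panel of RT-bearing polyproteins, one per family."""
    entries = []
    for family, length in _PANEL_POL_LENGTHS.items():
        sf = FAMILY_TO_SUPERFAMILY[family]
        if family in ("Gmr", "Mag"):
            pep = family_gagpol_protein(family, length)
        else:
            pep = family_pol_protein(family, length)
        pid = family.replace(" ", "_") + "_pol"
        entries.append(PanelEntry(ProteinSequence(pid, pep), family, sf))
    return entries


def write_panel_fasta(entries: list[PanelEntry], path: str | Path) -> None:
    lines = []
    for e in entries:
        fam = e.family.replace(" ", "_")
        lines.append(f">{e.protein.id} family={fam} superfamily={e.superfamily}")
        for i in range(0, len(e.protein.residues), 60):
            lines.append(e.protein.residues[i : i + 60])
    Path(path).write_text("\n".join(lines) + "\n")


def read_panel_fasta(path: str | Path) -> list[PanelEntry]:
    """Read a panel FASTA with ``family=`` / ``superfamily=`` header tags."""
    entries = []
    name, tags, chunks = None, {}, []
    lines = Path(path).read_text().splitlines() + [">"]
    for line in lines:
        if line.startswith(">"):
            if name is not None:
                fam = tags["family"].replace("_", " ")
                fam = fam if fam in FAMILY_TO_SUPERFAMILY else tags["family"]
                entries.append(
                    PanelEntry(ProteinSequence(name, "".join(chunks)), fam, tags["superfamily"])
                )
            fields = line[1:].split()
            name = fields[0] if fields else None
            tags = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
            chunks = []
        else:
            chunks.append(line.strip())
    return entries


def load_bundled_panel() -> list[PanelEntry]:
    ref = resources.files("tetraltr.data") / BUNDLED_PANEL
    with resources.as_file(ref) as p:
        return read_panel_fasta(p)


def write_bundled_data(data_dir: str | Path) -> None:
    """Regenerate the bundled synthetic profile TSV and panel FASTA."""
    data_dir = Path(data_dir)
    from .profiles import BUNDLED_PROFILES

    save_models_tsv(build_default_models().values(), data_dir / BUNDLED_PROFILES)
    write_panel_fasta(build_reference_panel(), data_dir / BUNDLED_PANEL)
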