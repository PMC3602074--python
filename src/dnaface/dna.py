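"""Single- and double-stranded B-form DNA construction from sequence.

Residue ``k`` (0-based, 5'->3') is the packaged nucleotide template rotated
by ``k * twist`` about z and translated by ``k * rise`` along z.  The
defaults are the canonical B-DNA fiber values — 3.38 A rise and 36.0 deg
twist per residue — for which the templates were derived, so the chain
backbone connects (O3'(k)-P(k+1) bond) and a 180-deg dyad about x
generates the Watson-Crick partner strand.  The 5' residue is built
without a phosphate (5'-OH convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .chem import DNA_COMPLEMENT
from .core import Atom, Chain, Residue, Structure

_PHOSPHATE = {"P", "OP1", "OP2"}


@dataclass
class HelixParameters:
    rise_per_residue: float = 3.38    # Angstrom
    twist_per_residue: float = 36.0   # degrees
    form_label: str = "B"

    def __post_init__(self) -> None:
        if self.rise_per_residue <= 0:
            raise ValueError("rise_per_residue must be > 0")
        if not 0 < self.twist_per_residue <= 360:
            raise ValueError("twist_per_residue must lie in (0, 360]")


B_FORM = HelixParameters()

_template_cache: dict[str, list[tuple[str, str, np.ndarray]]] = {}


def nucleotide_template(res_name: str) -> list[tuple[str, str, np.ndarray]]:
    """Packaged template for DA/DC/DG/DT: list of (name, element, xyz)."""
    res_name = res_name.upper()
    if res_name not in _template_cache:
        ref = resources.files("dnaface").joinpath(
            f"data/templates/{res_name}.tsv")
        rows = []
        for line in ref.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, el, x, y, z = line.split("\t")
            rows.append((name, el, np.array([float(x), float(y), float(z)])))
        _template_cache[res_name] = rows
    return [(n, e, xyz.copy()) for n, e, xyz in _template_cache[res_name]]


def _helical_op(k: int, params: HelixParameters) -> tuple[np.ndarray, np.ndarray]:
    ang = np.deg2rad(k * params.twist_per_residue)
    c, s = np.cos(ang), np.sin(ang)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return rot, np.array([0.0, 0.0, k * params.rise_per_residue])


def _validate_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty DNA sequence")
    seq = sequence.upper()
    for pos, base in enumerate(seq):
        if base not in "ACGT":
            raise ValueError(
                f"invalid base {base!r} at position {pos + 1} (alphabet ACGT)")
    return seq


def _make_residue(base: str, seq_id: int, k: int, params: HelixParameters,
                  serial_start: int, dyad: bool,
                  with_phosphate: bool) -> tuple[Residue, int]:
    rot, trans = _helical_op(k, params)
    res = Residue(name="D" + base, seq_id=seq_id)
    serial = serial_start
    for name, el, xyz in nucleotide_template("D" + base):
        if not with_phosphate and name in _PHOSPHATE:
            continue
        if dyad:
            xyz = xyz * np.array([1.0, -1.0, -1.0])
        serial += 1
        res.atoms.append(Atom(
            serial=serial, name=name, element=el,
            coords=rot @ xyz + trans,
            is_hydrogen=(el == "H")))
    return res, serial


def build_ssdna(sequence: str, params: HelixParameters | None = None,
                chain_id: str = "S") -> Structure:
    """Build a single-stranded B-form chain, 5'->3', one residue per base."""
    params = params or B_FORM
    seq = _validate_sequence(sequence)
    chain = Chain(chain_id=chain_id)
    serial = 0
    for k, base in enumerate(seq):
        res, serial = _make_residue(base, k + 1, k, params, serial,
                                    dyad=False, with_phosphate=(k > 0))
        chain.residues.append(res)
    return Structure(chains=[chain], title=f"ssDNA {seq} ({params.form_label}-form)")


def build_duplex(sequence: str, params: HelixParameters | None = None,
                 chain_ids: tuple[str, str] = ("S", "T")) -> Structure:
    """Build an antiparallel Watson-Crick duplex.

    The partner of residue k is the complementary template taken through
    the 180-deg dyad about x, then through the same helical operator; the
    complement chain is emitted in its own 5'->3' order.
    """
    params = params or B_FORM
    seq = _validate_sequence(sequence)
    fwd = build_ssdna(seq, params, chain_id=chain_ids[0])
    serial = fwd.atom_count()
    rev = Chain(chain_id=chain_ids[1])
    n = len(seq)
    # complement strand 5'->3' pairs with sequence positions n-1 ... 0
    for idx, k in enumerate(range(n - 1, -1, -1)):
        base = DNA_COMPLEMENT[seq[k]]
        res, serial = _make_residue(base, idx + 1, k, params, serial,
                                    dyad=True, with_phosphate=(idx > 0))
        rev.residues.append(res)
    return Structure(chains=fwd.chains + [rev],
                     title=f"dsDNA {seq} ({params.form_label}-form)")


def chain_sequence(structure: Structure, chain_id: str) -> str:
    """Read a nucleic chain's sequence 5'->3' (1-letter)."""
    return "".join(r.name[-1] for r in structure.chain(chain_id).residues)
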