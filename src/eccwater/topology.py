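"""GROMACS topology (.itp) and run-settings (.mdp) emission for four-site water.

The rigid geometry is encoded the way GROMACS expects for TIP4P-family
models: a SETTLE constraint block for the O-H / H-H distances and a type-1
three-body virtual site placing M on the H-O-H bisector,
``r_M = r_O + a (r_H1 - r_O) + b (r_H2 - r_O)`` with
``a = b = d_OM / (2 d_OH cos(θ/2))``.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Optional

from .watermodel import WaterModelParams

__all__ = ["write_topology", "parse_topology", "write_mdp_template"]

_ITP_TEMPLATE = """\
; Four-site rigid water model '{name}'
; sigma = {sigma:.6f} nm, epsilon = {epsilon:.6f} kJ/mol
; d_OH = {d_OH:.6f} nm, d_OM = {d_OM:.6f} nm, theta = {theta:.6f} deg
[ atomtypes ]
; name  at.num  mass      charge   ptype  sigma        epsilon
OW_{name}    8   15.99940  0.000000  A  {sigma:.6f}  {epsilon:.6f}
HW_{name}    1    1.00800  0.000000  A  0.000000  0.000000
MW_{name}    0    0.00000  0.000000  D  0.000000  0.000000

[ moleculetype ]
; molname   nrexcl
SOL     2

[ atoms ]
; nr  type        resnr  residue  atom  cgnr  charge       mass
  1   OW_{name}   1      SOL      OW    1     0.000000     15.99940
  2   HW_{name}   1      SOL      HW1   1     {q_H:.6f}     1.00800
  3   HW_{name}   1      SOL      HW2   1     {q_H:.6f}     1.00800
  4   MW_{name}   1      SOL      MW    1     {q_M:.6f}     0.00000

[ settles ]
; i  funct  doh          dhh
1    1      {doh:.6f}  {dhh:.6f}

[ virtual_sites3 ]
; site  from              funct  a            b
4       1     2     3     1      {vsite_a:.6f}  {vsite_a:.6f}

[ exclusions ]
1  2  3  4
2  1  3  4
3  1  2  4
4  1  2  3
"""

_MDP_TEMPLATE = """\
; NpT production settings for water-model property evaluation
; (832 molecules in a cubic box, 21 ns of which 1 ns equilibration)
integrator               = md
dt                       = 0.002
nsteps                   = 10500000
cutoff-scheme            = Verlet
coulombtype              = PME
rcoulomb                 = 1.2
vdwtype                  = PME
rvdw                     = 1.2
tcoupl                   = nose-hoover
tc-grps                  = System
tau-t                    = 1.0
ref-t                    = 300.0
pcoupl                   = parrinello-rahman
tau-p                    = 5.0
compressibility          = 5e-05
ref-p                    = 1.0
constraints              = none
"""


def _vsite_coefficient(params: WaterModelParams) -> float:
    half = math.radians(params.theta) / 2.0
    return params.d_OM / (2.0 * params.d_OH * math.cos(half))


def write_topology(
    params: WaterModelParams,
    path,
    name: str = "WAT",
    mdp_path: Optional[str] = None,
    write_mdp: bool = True,
) -> Path:
    """Write a self-contained GROMACS .itp for ``params`` and return its path.

    Unless ``write_mdp`` is false, a companion run-settings template with
    the reference NpT protocol is written next to it (``<stem>.mdp`` or
    ``mdp_path``).
    """
    path = Path(path)
    half = math.radians(params.theta) / 2.0
    content = _ITP_TEMPLATE.format(
        name=name,
        sigma=params.sigma,
        epsilon=params.epsilon,
        q_H=params.q_H,
        q_M=params.q_M,
        d_OH=params.d_OH,
        d_OM=params.d_OM,
        theta=params.theta,
        doh=params.d_OH,
        dhh=2.0 * params.d_OH * math.sin(half),
        vsite_a=_vsite_coefficient(params),
    )
    path.write_text(content)
    if write_mdp:
        target = Path(mdp_path) if mdp_path is not None else path.with_suffix(".mdp")
        target.write_text(_MDP_TEMPLATE)
    return path


def write_mdp_template(path) -> Path:
    """Write only the run-settings template."""
    path = Path(path)
    path.write_text(_MDP_TEMPLATE)
    return path


def parse_topology(path) -> WaterModelParams:
    """Recover the six parameters from an .itp produced by :func:`write_topology`.

    Round-trips to the 6-decimal precision of the file format.
    """
    text = Path(path).read_text()

    def _section(header: str) -> str:
        m = re.search(rf"\[ {header} \](.*?)(?=\n\[|\Z)", text, flags=re.S)
        if m is None:
            raise ValueError(f"missing [ {header} ] section in {path}")
        return m.group(1)

    atomtypes = _section("atomtypes")
    m = re.search(r"^OW_\S+\s+\d+\s+\S+\s+\S+\s+A\s+(\S+)\s+(\S+)", atomtypes, flags=re.M)
    if m is None:
        raise ValueError("could not locate the oxygen atomtype line")
    sigma, epsilon = float(m.group(1)), float(m.group(2))

    atoms = _section("atoms")
    charges = [float(line.split()[6]) for line in atoms.strip().splitlines()
               if line.strip() and not line.strip().startswith(";")]
    q_H = charges[1]

    settles = _section("settles")
    row = [line.split() for line in settles.strip().splitlines()
           if line.strip() and not line.strip().startswith(";")][0]
    doh, dhh = float(row[2]), float(row[3])
    theta = math.degrees(2.0 * math.asin(dhh / (2.0 * doh)))

    vsites = _section("virtual_sites3")
    row = [line.split() for line in vsites.strip().splitlines()
           if line.strip() and not line.strip().startswith(";")][0]
    a = float(row[5])
    d_OM = a * 2.0 * doh * math.cos(math.radians(theta) / 2.0)

    return WaterModelParams(sigma=sigma, epsilon=epsilon, q_H=q_H,
                            d_OH=doh, d_OM=d_OM, theta=theta)
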