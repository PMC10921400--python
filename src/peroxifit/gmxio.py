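"""Text-format readers and writers: itp/top topologies, gro coordinates and
xvg time series in the conventional MD-engine dialects.

All writers are deterministic (fixed formatting, 6 significant digits for
parameters) so two writes of identical inputs are byte-identical, and every
reader is the inverse of its writer on this dialect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .forcefield import (
    ExclusionPolicy,
    ForceConstants,
    ModelParameters,
    expand_rb_coefficients,
)

__all__ = [
    "write_topology",
    "read_topology",
    "write_gro",
    "read_gro",
    "write_xvg",
    "read_xvg",
]

_MASS = {"O": 15.9994, "H": 1.008}
_ATOMS = ("H1", "O1", "O2", "H2")
_ELEMENTS = ("H", "O", "O", "H")

#: All intramolecular site pairs of the 4-site chain, 1-based.
_ALL_PAIRS = ((1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4))


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_topology(
    params: ModelParameters,
    fc: ForceConstants,
    policy: ExclusionPolicy = ExclusionPolicy(),
    path=None,
) -> str:
    """Emit the H2O2 model as an itp-dialect topology string (and file).

    Sections: defaults (with fudgeQQ), atomtypes (O LJ parameters, H zero),
    moleculetype, atoms (+-q_H charges), bonds, angles, the expanded
    six-coefficient RB dihedral, and exclusions.  Under ``opls_14_half`` the
    1-4 H1-H2 pair moves from the exclusions to a pairs section.
    """
    c = expand_rb_coefficients(params.c2)
    q = params.q_H
    lines = [
        "; peroxifit H2O2 topology",
        "[ defaults ]",
        "; nbfunc comb-rule gen-pairs fudgeLJ fudgeQQ",
        f"1 3 no 0.0 {_fmt(policy.fudge_qq if policy.mode == 'opls_14_half' else 0.5)}",
        "",
        "[ atomtypes ]",
        "; name at.num mass charge ptype sigma epsilon",
        f"OP 8 {_fmt(_MASS['O'])} {_fmt(-q)} A {_fmt(params.sigma_OO)} {_fmt(params.eps_OO)}",
        f"HP 1 {_fmt(_MASS['H'])} {_fmt(q)} A 0 0",
        "",
        "[ moleculetype ]",
        "; name nrexcl",
        "HPO 3",
        "",
        "[ atoms ]",
        "; nr type resnr residue atom cgnr charge mass",
    ]
    types = ("HP", "OP", "OP", "HP")
    charges = (q, -q, -q, q)
    for i, (t, at, el, ch) in enumerate(zip(types, _ATOMS, _ELEMENTS, charges), start=1):
        lines.append(f"{i} {t} 1 HPO {at} {i} {_fmt(ch)} {_fmt(_MASS[el])}")
    lines += [
        "",
        "[ bonds ]",
        "; ai aj funct b0 kb",
        f"1 2 1 {_fmt(params.d_OH)} {_fmt(fc.kb_OH)}",
        f"2 3 1 {_fmt(params.d_OO)} {_fmt(fc.kb_OO)}",
        f"3 4 1 {_fmt(params.d_OH)} {_fmt(fc.kb_OH)}",
        "",
        "[ angles ]",
        "; ai aj ak funct th0 ka",
        f"1 2 3 1 {_fmt(params.a_HOO)} {_fmt(fc.ka_HOO)}",
        f"2 3 4 1 {_fmt(params.a_HOO)} {_fmt(fc.ka_HOO)}",
        "",
        "[ dihedrals ]",
        "; ai aj ak al funct c0 c1 c2 c3 c4 c5",
        "1 2 3 4 3 " + " ".join(_fmt(x) for x in c),
        "",
    ]
    if policy.mode == "opls_14_half":
        lines += [
            "[ pairs ]",
            "; ai aj funct",
            "1 4 1",
            "",
        ]
    lines.append("[ exclusions ]")
    excluded = [p for p in _ALL_PAIRS if not (policy.mode == "opls_14_half" and p == (1, 4))]
    by_first: dict[int, list[int]] = {}
    for i, j in excluded:
        by_first.setdefault(i, []).append(j)
    for i in sorted(by_first):
        lines.append(f"{i} " + " ".join(str(j) for j in sorted(by_first[i])))
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _sections(text: str) -> dict:
    """Split itp text into {section: [token rows]} honoring ';' comments."""
    sections: dict[str, list[list[str]]] = {}
    current = None
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split(";")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise ValueError(f"malformed section header at line {ln}: {raw!r}")
            current = line.strip("[] ").strip()
            sections.setdefault(current, [])
        else:
            if current is None:
                raise ValueError(f"data outside any section at line {ln}: {raw!r}")
            sections[current].append(line.split())
    return sections


def read_topology(path):
    """Parse an itp-dialect topology back to (ModelParameters, ForceConstants,
    ExclusionPolicy); inverse of :func:`write_topology` on its own output."""
    with open(path) as fh:
        text = fh.read()
    sec = _sections(text)
    for required in ("atoms", "bonds", "angles", "dihedrals"):
        if required not in sec:
            raise ValueError(f"missing [ {required} ] section")
    q_H = max(float(row[6]) for row in sec["atoms"])
    sigma = eps = None
    if "atomtypes" in sec:
        for row in sec["atomtypes"]:
            if float(row[5]) > 0:
                sigma, eps = float(row[5]), float(row[6])
    bonds = {(int(r[0]), int(r[1])): (float(r[3]), float(r[4])) for r in sec["bonds"]}
    d_OH, kb_OH = bonds[(1, 2)]
    d_OO, kb_OO = bonds[(2, 3)]
    a_HOO, ka = float(sec["angles"][0][4]), float(sec["angles"][0][5])
    dih = sec["dihedrals"][0]
    if len(dih) < 11:
        raise ValueError("dihedral row must carry six RB coefficients")
    c2 = float(dih[7])
    fudge = 0.5
    if "defaults" in sec:
        fudge = float(sec["defaults"][0][4])
    mode = "opls_14_half" if "pairs" in sec else "exclude_all_intra"
    return (
        ModelParameters(
            c2=c2, q_H=q_H, sigma_OO=sigma, eps_OO=eps, d_OO=d_OO, d_OH=d_OH, a_HOO=a_HOO
        ),
        ForceConstants(kb_OO=kb_OO, kb_OH=kb_OH, ka_HOO=ka),
        ExclusionPolicy(mode=mode, fudge_qq=fudge),
    )


def read_rb_coefficients(path) -> tuple:
    """The six raw RB coefficients from a topology's dihedral row (no
    constraint check: files with c4 != 0 are parsed faithfully)."""
    with open(path) as fh:
        sec = _sections(fh.read())
    if "dihedrals" not in sec:
        raise ValueError("missing [ dihedrals ] section")
    return tuple(float(x) for x in sec["dihedrals"][0][5:11])


# -- gro ---------------------------------------------------------------------

_RESNAME = {"H2O2": "HPO", "H2O": "SOL"}
_SPECIES = {v: k for k, v in _RESNAME.items()}


def write_gro(
    positions: np.ndarray,
    species,
    elements,
    molecule_ids,
    box,
    path=None,
    title: str = "peroxifit configuration",
) -> str:
    """Write a fixed-column gro coordinate file (nm, 3 decimals)."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    lines = [title, f"{n:5d}"]
    counters: dict[str, int] = {}
    for i in range(n):
        res = _RESNAME[str(species[i])]
        mol = int(molecule_ids[i])
        counters[f"{mol}"] = counters.get(f"{mol}", 0) + 1
        name = f"{elements[i]}{counters[f'{mol}']}"
        x, y, z = positions[i]
        lines.append(
            f"{(mol % 100000):5d}{res:<5s}{name:>5s}{((i + 1) % 100000):5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    bx, by, bz = np.asarray(box, dtype=float)
    lines.append(f"{bx:10.5f}{by:10.5f}{bz:10.5f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_gro(path) -> dict:
    """Read a gro file into positions, species/element labels, molecule ids
    and the box vector; inverse of :func:`write_gro` to format precision."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise ValueError("empty or truncated gro file")
    n = int(lines[1])
    if len(lines) < n + 3:
        raise ValueError("gro file shorter than its declared atom count")
    positions = np.empty((n, 3))
    species, elements, mol_ids = [], [], []
    for i in range(n):
        ln = lines[2 + i]
        mol_ids.append(int(ln[0:5]))
        res = ln[5:10].strip()
        name = ln[10:15].strip()
        species.append(_SPECIES.get(res, res))
        elements.append(name[0])
        positions[i] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
    box = np.array([float(x) for x in lines[2 + n].split()[:3]])
    return {
        "positions": positions,
        "species": np.array(species),
        "elements": np.array(elements),
        "molecule_ids": np.array(mol_ids),
        "box": box,
    }


# -- xvg ---------------------------------------------------------------------


def write_xvg(path, time, columns: dict, title: str = "", xlabel: str = "Time (ps)") -> None:
    """Write a legend-bearing xvg series: '#'/'@' headers then numeric rows."""
    names = list(columns)
    with open(path, "w") as fh:
        fh.write(f"# peroxifit xvg\n@    title \"{title}\"\n")
        fh.write(f"@    xaxis  label \"{xlabel}\"\n")
        for i, name in enumerate(names):
            fh.write(f"@ s{i} legend \"{name}\"\n")
        data = np.column_stack([np.asarray(time, dtype=float)] + [columns[n] for n in names])
        for row in data:
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


def read_xvg(path) -> dict:
    """Read an xvg file; columns are named from legends when present.

    Returns {'time': array, '<legend or col#>': array, ...}.
    """
    legends = []
    rows = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                continue
            if line.startswith("@"):
                if "legend" in line and line.split()[1].startswith("s"):
                    legends.append(line.split('"')[1])
                continue
            rows.append([float(x) for x in line.split()])
    if not rows:
        raise ValueError(f"empty xvg file: {path}")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("inconsistent column count in xvg file")
    data = np.array(rows)
    out = {"time": data[:, 0]}
    for j in range(1, width):
        name = legends[j - 1] if j - 1 < len(legends) else f"col{j}"
        out[name] = data[:, j]
    return out
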