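"""File formats: restraint TSV tables, ensemble SDF/CSV, dd reports.

All user-facing atom indices are 1-based.  RDC tables carry one row per
coupling with columns (atom_i, atom_j, D_Hz, medium, class); ``atom_i`` is the
carbon of the CH(n) group and ``atom_j`` one of its bonded partners — for
"methylene-sum" and "methyl" rows the remaining group protons are resolved
from the molecular graph.  NOE tables carry (group_i, group_j, d_A) with
proton groups written as "+"-joined 1-based indices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import StructureRecord
from .energy import NOERestraint, RDCRestraint
from .moltop import MolecularGraph

RDC_COLUMNS = ["atom_i", "atom_j", "D_Hz", "medium", "class"]
NOE_COLUMNS = ["group_i", "group_j", "d_A"]


def write_rdc_tsv(path, rdcs: list[RDCRestraint]) -> None:
    rows = []
    for r in rdcs:
        if r.klass == "methyl":
            i, j = r.pairs[0][0], r.h_atoms[0]
        else:
            i, j = r.pairs[0]
        rows.append({"atom_i": i + 1, "atom_j": j + 1, "D_Hz": r.d_exp,
                     "medium": r.medium, "class": r.klass})
    pd.DataFrame(rows, columns=RDC_COLUMNS).to_csv(path, sep="\t", index=False)


def read_rdc_tsv(path, graph: MolecularGraph, k: float = 1.0) -> list[RDCRestraint]:
    df = pd.read_csv(path, sep="\t")
    missing = set(RDC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"RDC table {path} lacks columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        i = int(row.atom_i) - 1
        j = int(row.atom_j) - 1
        klass = str(row["class"])
        if klass == "single":
            pairs = ((i, j),)
            h_atoms = ()
        elif klass == "methylene-sum":
            hs = [n for n in graph.neighbors(i) if graph.symbols[n] == "H"]
            if len(hs) != 2:
                raise ValueError(
                    f"atom {i + 1} is not a methylene carbon (found {len(hs)} H)")
            pairs = ((i, hs[0]), (i, hs[1]))
            h_atoms = ()
        elif klass == "methyl":
            hs = [n for n in graph.neighbors(i) if graph.symbols[n] == "H"]
            heavies = [n for n in graph.neighbors(i) if graph.symbols[n] != "H"]
            if len(hs) != 3 or len(heavies) != 1:
                raise ValueError(f"atom {i + 1} is not a methyl carbon")
            pairs = ((i, heavies[0]),)
            h_atoms = tuple(hs)
        else:
            raise ValueError(f"unknown RDC class '{klass}'")
        out.append(RDCRestraint(pairs, float(row.D_Hz), str(row.medium),
                                klass, k, h_atoms))
    return out


def write_noe_tsv(path, noes: list[NOERestraint]) -> None:
    rows = [{"group_i": "+".join(str(a + 1) for a in r.group_i),
             "group_j": "+".join(str(a + 1) for a in r.group_j),
             "d_A": r.d_exp} for r in noes]
    pd.DataFrame(rows, columns=NOE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_noe_tsv(path, k: float = 100.0) -> list[NOERestraint]:
    df = pd.read_csv(path, sep="\t")
    missing = set(NOE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"NOE table {path} lacks columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        gi = tuple(int(t) - 1 for t in str(row.group_i).split("+"))
        gj = tuple(int(t) - 1 for t in str(row.group_j).split("+"))
        out.append(NOERestraint(gi, gj, float(row.d_A), k))
    return out


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def _graph_to_rdkit(graph: MolecularGraph):
    from rdkit import Chem
    from rdkit.Chem import AllChem  # noqa: F401

    rw = Chem.RWMol()
    for s in graph.symbols:
        rw.AddAtom(Chem.Atom(s))
    for b in graph.bonds:
        i, j = tuple(b)
        rw.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    mol = rw.GetMol()
    for a in mol.GetAtoms():
        a.SetNoImplicit(True)
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                     | Chem.SanitizeFlags.SANITIZE_SETAROMATICITY)
    return mol


def write_ensemble(outdir, graph: MolecularGraph, records: list[StructureRecord]) -> None:
    """Multi-record SDF of coordinates + CSV sidecar of energies and keys."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mol = _graph_to_rdkit(graph)
    writer = Chem.SDWriter(str(outdir / "ensemble.sdf"))
    writer.SetKekulize(False)
    rows = []
    for rec in records:
        conf = Chem.Conformer(graph.n_atoms)
        for i in range(graph.n_atoms):
            x, y, z = rec.coords[i]
            conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
        mol.RemoveAllConformers()
        mol.AddConformer(conf, assignId=True)
        mol.SetProp("_Name", f"structure_{rec.replicate}")
        mol.SetProp("configuration", rec.configuration or "")
        mol.SetProp("E_total", f"{rec.energy.etotal:.9g}")
        writer.write(mol)
        rows.append({
            "replicate": rec.replicate, "seed": rec.seed,
            "configuration": rec.configuration,
            "E_total": rec.energy.etotal, "E_dist": rec.energy.edist,
            "E_chir": rec.energy.echir, "E_noe": rec.energy.enoe,
            "E_rdc": rec.energy.erdc, "converged": rec.converged,
        })
    writer.close()
    pd.DataFrame(rows).to_csv(outdir / "energies.csv", index=False)


def read_energies(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "E_total" not in df.columns or "configuration" not in df.columns:
        raise ValueError(f"{path} is not an ensemble energy table")
    return df


def write_dd_report(outdir, summary, uncertainty=None) -> None:
    """dd report as CSV and JSON: key, count, dd, std."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unc = uncertainty or summary.uncertainty or {}
    rows = [{"configuration": k, "count": summary.counts.get(k, 0),
             "dd": v, "std": unc.get(k, float("nan"))}
            for k, v in sorted(summary.dd.items(), key=lambda kv: -kv[1])]
    pd.DataFrame(rows).to_csv(outdir / "dd.csv", index=False)
    payload = {
        "n_dg": summary.n_dg, "z": summary.z,
        "dd": summary.dd, "counts": summary.counts,
        "uncertainty": {k: float(v) for k, v in unc.items()},
    }
    (outdir / "dd.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_energy_rank(outdir, records: list[StructureRecord]) -> None:
    """Energy-sorted rank table with step differences ΔE_N = E_N - E_(N-1)."""
    e = np.sort([r.energy.etotal for r in records])
    df = pd.DataFrame({"rank": np.arange(1, len(e) + 1), "E_total": e,
                       "dE_step": np.concatenate([[0.0], np.diff(e)])})
    Path(outdir).mkdir(parents=True, exist_ok=True)
    df.to_csv(Path(outdir) / "energy_rank.csv", index=False)


def write_manifest(outdir, config: dict) -> None:
    import fcdg

    payload = dict(config)
    payload["fcdg_version"] = getattr(fcdg, "__version__", "unknown")
    payload["numpy_version"] = np.__version__
    Path(outdir).mkdir(parents=True, exist_ok=True)
    (Path(outdir) / "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
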