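"""Regenerate the packaged 3D-1D score table (data/profile3d_scores.tsv).

The table scores the compatibility of each amino-acid type with one of 18
structural environments (3 burial levels x 2 environment polarities x 3
secondary-structure classes). Scores are a smooth function of the mismatch
between residue hydropathy and environment burial/polarity, with a small
helix former bonus, spanning roughly [-0.75, 0.7] per residue as in
published 3D-1D profile tables.
"""

from pathlib import Path

# Kyte-Doolittle hydropathy, min-max normalised to [0, 1]
KD = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}
HELIX_FORMERS = {"ALA", "GLU", "LEU", "MET", "GLN", "LYS", "ARG", "HIS"}

AA_ORDER = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
            "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
            "TYR", "VAL"]
BURIAL_VALUE = {"exposed": 0.0, "partial": 0.5, "buried": 1.0}


def main() -> None:
    lo, hi = min(KD.values()), max(KD.values())
    h = {aa: (v - lo) / (hi - lo) for aa, v in KD.items()}
    envs = [f"{b}-{p}-{s}"
            for b in ("exposed", "partial", "buried")
            for p in ("nonpolar", "polar")
            for s in ("helix", "sheet", "other")]
    lines = ["# 3D-1D environment score table (regenerate with"
             " scripts/make_profile_table.py)",
             "aa\t" + "\t".join(envs)]
    for aa in AA_ORDER:
        row = [aa]
        for env in envs:
            burial, pol, ss = env.split("-")
            b = BURIAL_VALUE[burial]
            e = 1.0 if pol == "polar" else 0.0
            score = 0.65 - 1.1 * abs(h[aa] - b) - 0.3 * abs((1.0 - h[aa]) - e)
            if ss == "helix" and aa in HELIX_FORMERS:
                score += 0.05
            row.append(f"{score:.3f}")
        lines.append("\t".join(row))
    out = Path(__file__).resolve().parents[1] / "src/xlinkdock/data/profile3d_scores.tsv"
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
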