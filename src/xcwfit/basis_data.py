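"""Embedded Gaussian basis-set library.

Contracted-Gaussian parameters for the Pople family used in this package,
transcribed from the published tabulations (Hehre et al. for STO-3G and
6-31G; Krishnan, Binkley, Seeger & Pople for 6-311G; the standard diffuse
and split polarization exponents for the ++ and (2d,2p) extensions).

Each entry maps an element symbol to a list of shells
``(ang, exponents, coefficients)`` where ``ang`` is one of ``"S" | "P" |
"D" | "SP"``; ``SP`` shells share exponents between an s and a p
contraction and carry ``(s_coeffs, p_coeffs)``.
"""

STO_3G = {
    "H": [
        ("S", [3.425250914, 0.6239137298, 0.1688554040],
              [0.1543289673, 0.5353281423, 0.4446345422]),
    ],
    "He": [
        ("S", [6.362421394, 1.158922999, 0.3136497915],
              [0.1543289673, 0.5353281423, 0.4446345422]),
    ],
    "C": [
        ("S", [71.61683735, 13.04509632, 3.530512160],
              [0.1543289673, 0.5353281423, 0.4446345422]),
        ("SP", [2.941249355, 0.6834830964, 0.2222899159],
               ([-0.09996722919, 0.3995128261, 0.7001154689],
                [0.1559162750, 0.6076837186, 0.3919573931])),
    ],
    "N": [
        ("S", [99.10616896, 18.05231239, 4.885660238],
              [0.1543289673, 0.5353281423, 0.4446345422]),
        ("SP", [3.780455879, 0.8784966449, 0.2857143744],
               ([-0.09996722919, 0.3995128261, 0.7001154689],
                [0.1559162750, 0.6076837186, 0.3919573931])),
    ],
    "O": [
        ("S", [130.7093214, 23.80886605, 6.443608313],
              [0.1543289673, 0.5353281423, 0.4446345422]),
        ("SP", [5.033151319, 1.169596125, 0.3803889600],
               ([-0.09996722919, 0.3995128261, 0.7001154689],
                [0.1559162750, 0.6076837186, 0.3919573931])),
    ],
}

_6_31G = {
    "H": [
        ("S", [18.73113696, 2.825394365, 0.6401216923],
              [0.03349460434, 0.2347269535, 0.8137573261]),
        ("S", [0.1612777588], [1.0]),
    ],
    "He": [
        ("S", [38.42163400, 5.778030000, 1.241774000],
              [0.04013973935, 0.2612460970, 0.7931846246]),
        ("S", [0.2979640000], [1.0]),
    ],
    "C": [
        ("S", [3047.524880, 457.3695180, 103.9486850, 29.21015530,
               9.286662960, 3.163926960],
              [0.001834737132, 0.01403732281, 0.06884262226, 0.2321844432,
               0.4679413484, 0.3623119853]),
        ("SP", [7.868272350, 1.881288540, 0.5442492580],
               ([-0.1193324198, -0.1608541517, 1.143456438],
                [0.06899906659, 0.3164239610, 0.7443082909])),
        ("SP", [0.1687144782], ([1.0], [1.0])),
    ],
    "N": [
        ("S", [4173.511460, 627.4579110, 142.9020930, 40.23432930,
               12.82021290, 4.390437010],
              [0.001834772160, 0.01399462700, 0.06858655181, 0.2322408730,
               0.4690699481, 0.3604551991]),
        ("SP", [11.62636186, 2.716279807, 0.7722183966],
               ([-0.1149611817, -0.1691174786, 1.145851947],
                [0.06757974388, 0.3239072959, 0.7408951398])),
        ("SP", [0.2120314975], ([1.0], [1.0])),
    ],
    "O": [
        ("S", [5484.671660, 825.2349460, 188.0469580, 52.96450000,
               16.89757040, 5.799635340],
              [0.001831074430, 0.01395017220, 0.06844507810, 0.2327143360,
               0.4701928980, 0.3585208530]),
        ("SP", [15.53961625, 3.599933586, 1.013761750],
               ([-0.1107775495, -0.1480262627, 1.130767015],
                [0.07087426823, 0.3397528391, 0.7271585773])),
        ("SP", [0.2700058226], ([1.0], [1.0])),
    ],
}

_6_311G = {
    "H": [
        ("S", [33.86500, 5.094790, 1.158790],
              [0.0254938, 0.190373, 0.852161]),
        ("S", [0.325840], [1.0]),
        ("S", [0.102741], [1.0]),
    ],
    "C": [
        ("S", [4563.240, 682.0240, 154.9730, 44.45530, 13.02900, 1.827730],
              [0.00196665, 0.0152306, 0.0761269, 0.2608010, 0.6164620,
               0.2210060]),
        ("SP", [20.96420, 4.803310, 1.459330],
               ([0.1146600, 0.9199990, -0.00303068],
                [0.0402487, 0.2375940, 0.8158540])),
        ("SP", [0.4834560], ([1.0], [1.0])),
        ("SP", [0.1455850], ([1.0], [1.0])),
    ],
    "N": [
        ("S", [6293.480, 949.0440, 218.7760, 63.69160, 18.28200, 2.720230],
              [0.00196979, 0.0149613, 0.0735006, 0.2489370, 0.6024600,
               0.2562020]),
        ("SP", [30.63310, 7.026140, 2.112050],
               ([0.1119060, 0.9216660, -0.00256919],
                [0.0383119, 0.2374030, 0.8175920])),
        ("SP", [0.6840090], ([1.0], [1.0])),
        ("SP", [0.2008780], ([1.0], [1.0])),
    ],
    "O": [
        ("S", [8588.500, 1297.230, 299.2960, 87.37710, 25.67890, 3.740040],
              [0.00189515, 0.0143859, 0.0707320, 0.2400010, 0.5947970,
               0.2808020]),
        ("SP", [42.11750, 9.628370, 2.853320],
               ([0.1138890, 0.9208110, -0.00327447],
                [0.0365114, 0.2371530, 0.8197020])),
        ("SP", [0.9056610], ([1.0], [1.0])),
        ("SP", [0.2556110], ([1.0], [1.0])),
    ],
}

#: Diffuse sp exponents for heavy atoms ("+") and diffuse s for H ("++").
DIFFUSE_SP = {"C": 0.0438, "N": 0.0639, "O": 0.0845}
DIFFUSE_S_H = {"H": 0.0360}

#: Single polarization exponents of 6-311G(d,p); the (2d,2p) sets split each
#: by the usual factor of two up and down.
POL_D = {"C": 0.626, "N": 0.913, "O": 1.292}
POL_P_H = {"H": 0.750}

#: 6-31G(d) d exponent (identical 0.8 for C, N, O).
POL_D_631 = {"C": 0.8, "N": 0.8, "O": 0.8}
POL_P_631_H = {"H": 1.1}


def _with_extensions(base, *, diffuse=False, npol=0, pol_h=True, family="6-311"):
    """Assemble an extended Pople set from a base table."""
    out = {}
    pol_d = POL_D if family == "6-311" else POL_D_631
    pol_p = POL_P_H if family == "6-311" else POL_P_631_H
    for elem, shells in base.items():
        shells = list(shells)
        if diffuse:
            if elem in DIFFUSE_SP:
                shells.append(("SP", [DIFFUSE_SP[elem]], ([1.0], [1.0])))
            elif elem in DIFFUSE_S_H:
                shells.append(("S", [DIFFUSE_S_H[elem]], [1.0]))
        if npol:
            if elem == "H":
                if not pol_h:
                    out[elem] = shells
                    continue
                alpha = pol_p[elem]
                exps = [alpha] if npol == 1 else [2.0 * alpha, alpha / 2.0]
                for a in exps:
                    shells.append(("P", [a], [1.0]))
            elif elem in pol_d:
                alpha = pol_d[elem]
                exps = [alpha] if npol == 1 else [2.0 * alpha, alpha / 2.0]
                for a in exps:
                    shells.append(("D", [a], [1.0]))
        out[elem] = shells
    return out


BASIS_LIBRARY = {
    "sto-3g": STO_3G,
    "6-31g": _6_31G,
    "6-31g(d)": _with_extensions(_6_31G, npol=1, pol_h=False, family="6-31"),
    "6-31g(d,p)": _with_extensions(_6_31G, npol=1, family="6-31"),
    "6-311g": _6_311G,
    "6-311g(d,p)": _with_extensions(_6_311G, npol=1),
    "6-311g(2d,2p)": _with_extensions(_6_311G, npol=2),
    "6-311++g(2d,2p)": _with_extensions(_6_311G, diffuse=True, npol=2),
}


def get_element_shells(basis_name: str, element: str):
    key = basis_name.lower()
    if key not in BASIS_LIBRARY:
        raise KeyError(
            f"basis {basis_name!r} not in library; available: "
            f"{sorted(BASIS_LIBRARY)}"
        )
    table = BASIS_LIBRARY[key]
    if element not in table:
        raise KeyError(f"element {element} not tabulated for basis {basis_name}")
    return table[element]
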