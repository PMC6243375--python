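"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: residue masses are
hard-coded published monoisotopic values, digestion validity is checked per
substring from first principles, and the binomial tail is summed term by
term with exact integer binomial coefficients.
"""

from math import comb

# published monoisotopic residue masses, independent of the package tables
AA_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.010565
PROTON = 1.007276


def peptide_mass_oracle(sequence: str, delta: float = 0.0) -> float:
    return sum(AA_MASS[aa] for aa in sequence) + WATER + delta


def by_ions_oracle(sequence: str, charges=(1,)) -> list[float]:
    """All b and y fragment m/z values by direct summation."""
    out = []
    n = len(sequence)
    for z in charges:
        for i in range(1, n):
            b = sum(AA_MASS[aa] for aa in sequence[:i])
            out.append((b + z * PROTON) / z)
        for i in range(1, n):
            y = sum(AA_MASS[aa] for aa in sequence[n - i :]) + WATER
            out.append((y + z * PROTON) / z)
    return out


def binomial_tail_oracle(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), summed term by term."""
    total = 0.0
    for j in range(k, n + 1):
        total += comb(n, j) * p**j * (1.0 - p) ** (n - j)
    return total


def substring_in_search_space(
    protein: str,
    i: int,
    j: int,
    tryp_mc: int = 2,
    oper_mc: int = 5,
    min_len: int = 6,
    max_len: int = 46,
) -> bool:
    """Whether protein[i:j] (0-based, half-open) is a valid dual-digestion
    product, checked from first principles.

    The substring must pass the length and S/T content filters and admit at
    least one derivation: a tryptic peptide [a, b) (K/R-terminated boundaries,
    <= tryp_mc internal K/R) containing it, such that the substring starts at
    the peptide start or at an S/T, ends at the peptide end or immediately
    before an S/T, and retains <= oper_mc internal S/T (positions 2..n).
    """
    n = len(protein)
    frag = protein[i:j]
    if not (min_len <= len(frag) <= max_len):
        return False
    if not any(aa in "ST" for aa in frag):
        return False
    if sum(1 for aa in frag[1:] if aa in "ST") > oper_mc:
        return False
    for a in range(0, i + 1):
        if a != 0 and protein[a - 1] not in "KR":
            continue
        for b in range(j, n + 1):
            if b != n and protein[b - 1] not in "KR":
                continue
            if sum(1 for aa in protein[a : b - 1] if aa in "KR") > tryp_mc:
                continue
            starts_ok = i == a or protein[i] in "ST"
            ends_ok = j == b or (j < n and protein[j] in "ST")
            if starts_ok and ends_ok:
                return True
    return False


def search_space_oracle(protein: str, **kwargs) -> set[str]:
    """Every valid dual-digestion product of ``protein`` by exhaustive
    substring enumeration."""
    n = len(protein)
    out = set()
    for i in range(n):
        for j in range(i + 1, n + 1):
            if substring_in_search_space(protein, i, j, **kwargs):
                out.add(protein[i:j])
    return out
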