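"""Independent brute-force oracles used to check the package's implementations.

These deliberately use different algorithms/representations than the package:
k-mer counting via a python dict over explicit windows, loop typing via a
dot-bracket string parsed into an explicit tree, confusion metrics via exact
rational arithmetic, and AUC via exhaustive pairwise comparison.
"""

from fractions import Fraction
from itertools import product
from math import isqrt


def kmer_frequencies(seq: str, alphabet: str, k: int):
    """Dictionary-count oracle for k-mer frequencies in declared-alphabet order."""
    counts = {}
    n_windows = len(seq) - k + 1
    for start in range(max(n_windows, 0)):
        counts[seq[start : start + k]] = counts.get(seq[start : start + k], 0) + 1
    out = []
    for kmer in product(alphabet, repeat=k):
        word = "".join(kmer)
        out.append(counts.get(word, 0) / n_windows if n_windows > 0 else 0.0)
    return out


def _dot_bracket(length: int, pairs) -> str:
    s = ["."] * (length + 1)
    for i, j in pairs:
        s[i], s[j] = "(", ")"
    return "".join(s[1:])


class _Node:
    def __init__(self, pair=None):
        self.pair = pair  # (i, j) or None for the root
        self.children = []
        self.unpaired = []  # unpaired positions directly inside this node


def loop_type_oracle(length: int, pairs) -> str:
    """Label loop types by parsing a dot-bracket string into an explicit tree."""
    db = _dot_bracket(length, set(pairs))
    root = _Node()
    stack = [root]
    for pos, ch in enumerate(db, start=1):
        if ch == "(":
            node = _Node(pair=[pos, None])
            stack[-1].children.append(node)
            stack.append(node)
        elif ch == ")":
            node = stack.pop()
            node.pair[1] = pos
        else:
            stack[-1].unpaired.append(pos)
    assert len(stack) == 1

    labels = {}
    for i, j in pairs:
        labels[i] = labels[j] = "S"

    # root level: E before the first / after the last paired position, X between
    if root.children:
        first = min(c.pair[0] for c in root.children)
        last = max(c.pair[1] for c in root.children)
    for pos in root.unpaired:
        if not root.children or pos < first or pos > last:
            labels[pos] = "E"
        else:
            labels[pos] = "X"

    def visit(node):
        for child in node.children:
            visit(child)
        if node.pair is None:
            return
        if not node.children:
            lab = "H"
        elif len(node.children) >= 2:
            lab = "M"
        else:
            (ci, cj) = node.children[0].pair
            left = [p for p in node.unpaired if p < ci]
            right = [p for p in node.unpaired if p > cj]
            lab = "I" if (left and right) else "B"
        for pos in node.unpaired:
            labels[pos] = lab

    visit(root)
    return "".join(labels[p] for p in range(1, length + 1))


def metrics_oracle(tp: int, fp: int, tn: int, fn: int):
    """Exact rational evaluation of the six confusion metrics; zero/zero -> 0."""

    def ratio(num, den):
        return Fraction(num, den) if den != 0 else Fraction(0)

    acc = ratio(tp + tn, tp + tn + fp + fn)
    tpr = ratio(tp, tp + fn)
    tnr = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    f1 = ratio(2 * tpr * ppv, tpr + ppv) if (tpr + ppv) != 0 else Fraction(0)
    mcc_den_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den_sq == 0:
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / (mcc_den_sq ** 0.5)
    return {
        "acc": float(acc),
        "tpr": float(tpr),
        "tnr": float(tnr),
        "ppv": float(ppv),
        "f1": float(f1),
        "mcc": float(mcc),
    }


def auc_oracle(labels, scores) -> float:
    """Exhaustive pairwise AUC: wins + half-ties over all (pos, neg) pairs."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
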