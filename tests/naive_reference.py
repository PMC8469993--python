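"""Independent straight-line reimplementation of the feature definitions.

Used only as a test oracle: plain Python loops, no shared code with the
package's vectorised implementation, and the BLOSUM62 values come from
Biopython rather than the packaged table.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_BLOSUM = substitution_matrices.load("BLOSUM62")


def naive_pspm(rows: list[str], pseudocount: float) -> list[list[float]]:
    """Per-column residue frequencies by direct counting; gaps/ambiguity ignored."""
    L = len(rows[0])
    matrix = []
    for i in range(L):
        counts = {aa: 0 for aa in AMINO_ACIDS}
        total = 0
        for row in rows:
            c = row[i]
            if c in counts:
                counts[c] += 1
                total += 1
        if total == 0:
            matrix.append([1.0 / 20.0] * 20)
        else:
            denom = total + 20 * pseudocount
            matrix.append([(counts[aa] + pseudocount) / denom for aa in AMINO_ACIDS])
    return matrix


def naive_entropy_stats(pspm: list[list[float]]) -> tuple[list[float], float, float]:
    entropies = []
    for row in pspm:
        e = 0.0
        for p in row:
            if p > 0.0:
                e -= p * math.log(p)
        entropies.append(e)
    L = len(entropies)
    mu = sum(entropies) / L
    sd = math.sqrt(sum((e - mu) ** 2 for e in entropies) / (L - 1)) if L > 1 else 0.0
    return entropies, mu, sd


def naive_blosum_inner(pspm_row: list[float], residue: str) -> float:
    return sum(p * _BLOSUM[residue, aa] for p, aa in zip(pspm_row, AMINO_ACIDS))


def naive_kl(p: list[float], q: list[float]) -> float:
    return sum(pj * math.log(pj / qj) for pj, qj in zip(p, q) if pj > 0.0)


def naive_msa_block(wt_rows, mut_rows, k, wt_res, mut_res, pseudocount):
    wt_pspm = naive_pspm(wt_rows, pseudocount)
    mut_pspm = naive_pspm(mut_rows, pseudocount)
    out = []
    stats = []
    for pspm in (wt_pspm, mut_pspm):
        e, mu, sd = naive_entropy_stats(pspm)
        e_k = e[k - 1]
        z_k = 0.0 if sd < 1e-12 else (e_k - mu) / sd
        stats.append((e_k, z_k, mu, sd))
        out.extend((e_k, z_k, mu, sd))
    out.extend(w - m for w, m in zip(stats[0], stats[1]))
    b_wt = naive_blosum_inner(wt_pspm[k - 1], wt_res)
    b_mut = naive_blosum_inner(mut_pspm[k - 1], mut_res)
    out.extend((b_wt, b_mut, b_wt - b_mut))
    return out


def naive_binding_block(wt_rows, mut_rows, k, wt_seq, mut_seq, predictions,
                        pseudocount):
    """predictions: mapping channel-name -> (calls list, propensities list),
    iterated in (dna, rna, generic) order."""
    wt_pspm = naive_pspm(wt_rows, pseudocount)
    mut_pspm = naive_pspm(mut_rows, pseudocount)
    L = len(wt_pspm)
    e_wt, _, _ = naive_entropy_stats(wt_pspm)
    e_mut, _, _ = naive_entropy_stats(mut_pspm)

    def shift(measure: str, i: int) -> float:
        if measure == "entropy":
            return abs(e_wt[i - 1] - e_mut[i - 1])
        if measure == "blosum":
            bw = naive_blosum_inner(wt_pspm[i - 1], wt_seq[i - 1])
            bm = naive_blosum_inner(mut_pspm[i - 1], mut_seq[i - 1])
            return abs(bw - bm)
        return naive_kl(wt_pspm[i - 1], mut_pspm[i - 1])

    screening, min_dists = [], []
    for ch in ("dna", "rna", "generic"):
        calls, props = predictions[ch]
        positions = [i + 1 for i, c in enumerate(calls) if c == 1]
        if not positions:
            screening.extend([0.0, float(L), 0.0] * 3)
        else:
            for measure in ("entropy", "blosum", "kl"):
                # smallest index wins ties, with values within 1e-9 of the
                # max counting as tied (mirrors the documented tie rule)
                values = [shift(measure, i) for i in positions]
                vmax = max(values)
                best_pos, best_val = next(
                    (i, v) for i, v in zip(positions, values) if v >= vmax - 1e-9
                )
                screening.extend([best_val, float(abs(best_pos - k)),
                                  props[best_pos - 1]])
        if positions:
            min_dists.append(float(min(abs(i - k) for i in positions)))
        else:
            min_dists.append(float(L))
    return screening + min_dists


def naive_feature_vector(record, msa_rows, predictions, pseudocount):
    """Full 60-vector. ``msa_rows``: dict with keys (source, 'wt'/'mut') ->
    list of aligned row strings; ``predictions``: channel-name -> (calls, props)."""
    out = []
    for source in ("psiblast", "hhblits"):
        out.extend(naive_msa_block(
            msa_rows[(source, "wt")], msa_rows[(source, "mut")],
            record.position, record.wt_residue, record.mut_residue, pseudocount,
        ))
    out.extend(naive_binding_block(
        msa_rows[("psiblast", "wt")], msa_rows[("psiblast", "mut")],
        record.position, record.wt_sequence, record.mutant_sequence,
        predictions, pseudocount,
    ))
    return out
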