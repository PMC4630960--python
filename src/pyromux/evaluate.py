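"""Genotype concordance against a gold-standard truth table."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

NO_CALL = "no_call"


def _canon(label: str) -> str:
    """Canonical genotype string: diploid alleles sorted, so C/T == T/C."""
    label = label.strip()
    if "/" in label:
        return "/".join(sorted(label.split("/")))
    return label


@dataclass
class ConcordanceReport:
    n_compared: int
    n_concordant: int
    per_snp: dict[str, tuple[int, int]]  # snp -> (n_compared, n_concordant)
    discordant: list[tuple[str, str, str, str]]  # (well, snp, truth, call)

    @property
    def percent(self) -> float:
        return 100.0 * self.n_concordant / self.n_compared

    def to_dict(self) -> dict:
        return {
            "n_compared": self.n_compared,
            "n_concordant": self.n_concordant,
            "percent": self.percent,
            "per_snp": {k: {"n": n, "concordant": c}
                        for k, (n, c) in self.per_snp.items()},
            "discordant": [
                {"well_id": w, "snp_id": s, "truth": t, "call": c}
                for w, s, t, c in self.discordant
            ],
        }


def concordance(
    calls: Mapping[tuple[str, str], str],
    truth: Mapping[tuple[str, str], str],
) -> ConcordanceReport:
    """Compare genotype labels keyed by (well_id, snp_id).

    The denominator is the key intersection.  ``no_call`` entries count as
    discordant and are listed.  Diploid labels compare order-insensitively.
    """
    keys = sorted(set(calls) & set(truth))
    if not keys:
        raise ValueError("no overlapping (well, SNP) keys between calls and truth")
    per_snp: dict[str, list[int]] = {}
    discordant = []
    n_conc = 0
    for well, snp in keys:
        c = _canon(str(calls[(well, snp)]))
        t = _canon(str(truth[(well, snp)]))
        ok = (c == t) and c != NO_CALL and t != NO_CALL
        stat = per_snp.setdefault(snp, [0, 0])
        stat[0] += 1
        if ok:
            stat[1] += 1
            n_conc += 1
        else:
            discordant.append((well, snp, t, c))
    return ConcordanceReport(
        n_compared=len(keys),
        n_concordant=n_conc,
        per_snp={k: (v[0], v[1]) for k, v in per_snp.items()},
        discordant=discordant,
    )
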