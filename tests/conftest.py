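import numpy as np
import pytest

from mtkit.selfref import MtVariantCall, ReferenceSequence

BASES = "ACGT"


def random_reference(rng, length=200, name="ref", circular=True):
    bases = "".join(rng.choice(list(BASES), size=length))
    return ReferenceSequence(name=name, bases=bases, circular=circular)


def random_homoplasmic_edits(rng, ref, n_edits=5):
    """Non-overlapping homoplasmic SNV/insertion/deletion calls on ``ref``,
    sorted by position, VCF-style (indels anchored on the preceding base)."""
    calls = []
    pos = 2  # keep position 1 untouched so deletions can anchor left
    for _ in range(n_edits):
        pos += int(rng.integers(3, max(4, ref.length // n_edits)))
        if pos > ref.length - 3:
            break
        kind = rng.choice(["snv", "ins", "del"])
        r = ref.bases[pos - 1]
        if kind == "snv":
            alt = str(rng.choice([b for b in BASES if b != r]))
            calls.append(MtVariantCall(ref.name, pos, r, alt, 0.99))
        elif kind == "ins":
            ins = "".join(rng.choice(list(BASES),
                                     size=int(rng.integers(1, 4))))
            calls.append(MtVariantCall(ref.name, pos, r, r + ins, 0.99))
        else:
            ndel = int(rng.integers(1, 3))
            r_all = ref.bases[pos - 1:pos + ndel]
            calls.append(MtVariantCall(ref.name, pos, r_all, r, 0.99))
            pos += ndel
    return calls


def apply_edits_bruteforce(ref_bases, calls):
    """Independent string-edit oracle: apply sorted non-overlapping calls."""
    parts, cur = [], 0
    for c in calls:
        s = c.pos - 1
        parts.append(ref_bases[cur:s])
        parts.append(c.alt_allele)
        cur = s + len(c.ref_allele)
    parts.append(ref_bases[cur:])
    return "".join(parts)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
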