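import math

import numpy as np
import pytest

from cubkit import CodingSequence, count_codons
from cubkit.code import default_code


@pytest.fixture(scope="session")
def code():
    return default_code()


def joint_usage(profile, code):
    """A profile's joint codon distribution (aa_freq x cuf) over 61 codons."""
    return np.array([
        profile.aa_freq[code.aa_of(c)]
        * (0.0 if math.isnan(profile.cuf[c]) else profile.cuf[c])
        for c in code.sense_codons])


def sample_genes(profile, n_genes, n_codons, rng, code, prefix="g"):
    """Multinomial gene sampler: aa composition then within-family codons."""
    aa = profile.aa_freq / profile.aa_freq.sum()
    seqs = []
    for i in range(n_genes):
        counts = rng.multinomial(n_codons, aa.to_numpy())
        codons = []
        for a, n_aa in zip(aa.index, counts):
            if n_aa == 0:
                continue
            fam = list(code.family(a))
            q = profile.cuf[fam].to_numpy()
            per = rng.multinomial(int(n_aa), q / q.sum())
            for codon, k in zip(fam, per):
                codons.extend([codon] * int(k))
        seqs.append(CodingSequence(f"{prefix}{i}", "".join(codons)))
    return seqs


@pytest.fixture
def small_table(code):
    rng = np.random.default_rng(7)
    from cubkit.simulate import gc3_family_profile
    genes = sample_genes(gc3_family_profile(0.5), 10, 120, rng, code)
    return count_codons(genes, code)
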