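"""One-off generator for the bundled synthetic reference FASTA (deterministic)."""
import numpy as np

AA = list("ACDEFGHIKLMNPQRSTVWY")
rng = np.random.default_rng(20230218)

SPEC = {
    "Cas12k": (639, 2),
    "TnsB": (560, 2),
    "TnsC": (430, 2),
    "TniQ": (220, 2),
    "CvkR": (185, 3),
    "Arc_1": (72, 3),
    "Arc_2": (70, 3),
}


def mutate(seq, frac):
    s = list(seq)
    idx = rng.choice(len(s), size=int(round(frac * len(s))), replace=False)
    for i in idx:
        choices = [a for a in AA if a != s[i]]
        s[i] = choices[rng.integers(len(choices))]
    return "".join(s)


with open("src/castkit/data/synthetic_refs.faa", "w") as fh:
    for family, (length, n) in SPEC.items():
        base = "M" + "".join(rng.choice(AA, size=length - 1))
        for i in range(1, n + 1):
            seq = base if i == 1 else mutate(base, 0.15)
            fh.write(f">{family}|synthetic-{i}\n")
            for j in range(0, len(seq), 70):
                fh.write(seq[j : j + 70] + "\n")
print("written")
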