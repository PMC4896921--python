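"""Characteristic repeat-length thresholds of a Bernoulli source.

For a sequence of length n, five lengths delimit its random repeat
structure: below the completion length every k-mer is repeated; the
profile of unique k-mers peaks at the fundamental length; beyond the
extinction length essentially no repeat survives.  The extinction
length is the quantity of practical interest: reads longer than it map
uniquely in a random background of the same composition.
"""

from trieprofile import compute_ratios, gc_model, make_model

# a biased binary source, and a DNA model for a GC-rich genome
for label, model, n in [
    ("binary p_max=0.7", make_model([0.7, 0.3]), 5_000_000),
    ("DNA GC=0.6664", gc_model(0.6664), 2_847_757),
]:
    r = compute_ratios(model, n)
    print(f"{label}, n={n}:")
    for name in ("min", "tilde", "bar", "max", "ext"):
        alpha = getattr(r, f"alpha_{name}")
        k = getattr(r, f"k_{name}")
        print(f"  alpha_{name:<6} = {alpha:7.4f}   k_{name:<6} = {k:6.2f}")
    print(
        f"  -> reads longer than {r.k_ext:.0f} characters are expected to be"
        " unique in a random sequence with this composition\n"
    )
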