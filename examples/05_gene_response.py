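"""Inverse sex-dependent marker-gene response to a western diet.

Computes the steady-state log2 fold change (western vs chow) of the three
marker transcripts.  Agpat and Prkaa fall in males but rise in females, while
Irs does the opposite - the qualitative signature that a sex-blind model
cannot reproduce.
"""

from liversim import DietSpec, MARKER_GENES, gene_response, load_reference

doc = load_reference()
print(f"{'gene':8s} {'male':>8s} {'female':>8s}   (log2 FC, western vs chow)")
fc = {sex: gene_response(doc, list(MARKER_GENES), DietSpec.chow(),
                         DietSpec.western(), sex) for sex in ("male", "female")}
for gid in MARKER_GENES:
    print(f"{gid:8s} {fc['male'][gid]:+8.3f} {fc['female'][gid]:+8.3f}")
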