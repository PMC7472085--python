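"""Print both classifier architectures with per-layer learnable counts.

The closed-form counts (e.g. conv: kh*kw*c_in*filters + filters; LSTM:
4H(I+H) + 4H) are cross-checked against the instantiated network's enumerated
parameter arrays — the two must agree to the integer.
"""

import pandas as pd

from emochart import nets

for build in (nets.build_eeg_2dcnn, nets.build_seq_1dcnn_lstm):
    spec = build()
    model = nets.instantiate(spec, seed=0)
    print(f"\n=== {spec.name} ===")
    print(pd.DataFrame(spec.to_rows()).to_string(index=False))
    print(f"total learnables (closed form):   {spec.total_learnables:>9,}")
    print(f"total parameters (instantiated):  {model.n_params():>9,}")
    assert model.n_params() == spec.total_learnables
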