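"""Analytic parameter accounting for the reference architectures.

An LSTM layer with input width n and m units carries 4·((n+m)·m + m)
trainable parameters (four gate blocks, one bias vector each); the simple
RNN carries exactly a quarter.  The table below compares the closed-form
counts with the element counts of the instantiated weight arrays — they
must agree integer-for-integer.
"""

from stemfill import (
    SequenceNetwork,
    count_model_params,
    reference_lstm_architecture,
    reference_rnn_architecture,
)

for label, arch in (("LSTM 256/128/64", reference_lstm_architecture()),
                    ("RNN  256/128/64", reference_rnn_architecture())):
    analytic, total = count_model_params(arch)
    instantiated = SequenceNetwork(arch, seed=0).layer_param_counts()
    print(f"\n{label}")
    print(f"{'layer':<10}{'analytic':>12}{'instantiated':>14}")
    for spec, a, b in zip(arch.layers, analytic, instantiated):
        print(f"{spec.kind:<10}{a:>12,}{b:>14,}")
    print(f"{'total':<10}{total:>12,}{sum(instantiated):>14,}")
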