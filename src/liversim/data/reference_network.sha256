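9a188c8ca53b1cf3788d976882c99084ecd4b3041d655afa0030f05246be7339  reference_network.json
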