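más de	over
mas de	over
por encima de	over
menos de	under
por debajo de	under
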