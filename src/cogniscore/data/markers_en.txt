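over	over
more than	over
above	over
under	under
less than	under
below	under
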