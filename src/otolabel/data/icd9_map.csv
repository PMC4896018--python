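region,code
outer,380.10
outer,380.22
outer,380.50
outer,380.9
outer,744.01
outer,744.02
middle,381.10
middle,381.4
middle,382.9
middle,384.20
middle,385.00
middle,385.22
middle,385.3
middle,387.0
inner,386.00
inner,386.30
inner,386.9
inner,388.5
inner,744.05
mastoid,383.00
mastoid,383.1
mastoid,383.30
mastoid,383.9
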