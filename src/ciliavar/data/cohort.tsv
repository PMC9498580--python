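patient_id	sex
T180101	male
T180201	male
T180301	male
T180401	male
T180701	female
T180801	male
T180901	male
T181001	female
T181101	male
T181201	male
T181401	male
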