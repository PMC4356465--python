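sample_id	total_reads	total_bp	nr_similar_reads
NPK9	46605	29467018	25914
NPK10	57341	37031295	31528
NPK12	79808	52179838	42611
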