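patient_id,drug,codrp_call,auc_call
200,afatinib,sensitive,sensitive
224,afatinib,resistant,resistant
240,afatinib,resistant,sensitive
246,afatinib,resistant,resistant
263,afatinib,resistant,resistant
266,afatinib,sensitive,resistant
278,afatinib,resistant,sensitive
282,afatinib,resistant,resistant
283,afatinib,resistant,resistant
305,afatinib,sensitive,sensitive
316,afatinib,sensitive,sensitive
331,afatinib,resistant,resistant
334,afatinib,sensitive,sensitive
340,afatinib,sensitive,sensitive
200,osimertinib,sensitive,
224,osimertinib,resistant,
240,osimertinib,resistant,
246,osimertinib,sensitive,
263,osimertinib,sensitive,
266,osimertinib,sensitive,
278,osimertinib,sensitive,
282,osimertinib,resistant,
283,osimertinib,resistant,
305,osimertinib,sensitive,
316,osimertinib,sensitive,
331,osimertinib,resistant,
334,osimertinib,sensitive,
340,osimertinib,sensitive,
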