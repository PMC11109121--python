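patient_id,sex,age,smoking,stage_at_sampling,mutations,drug,line,recist_label,tumor_change_pct,notes
200,male,68,current,IVB (T4N3M1c),EGFR exon19 deletion,afatinib,1,PR,,sampled at diagnosis; PR on first-line afatinib
224,male,64,ex,IVB (T4N3M1c),EGFR exon19 deletion;T790M,afatinib,1,PD,,initial PR; progression with T790M before sampling
224,male,64,ex,IVB (T4N3M1c),EGFR exon19 deletion;T790M,osimertinib,2,PD,,sampled at progression on osimertinib
240,female,56,never,IVB (T4N3M1c),EGFR exon19 deletion;T790M;ALK translocation,afatinib,1,PD,,initial PR; progression before sampling
240,female,56,never,IVB (T4N3M1c),EGFR exon19 deletion;T790M;ALK translocation,osimertinib,3,PD,,initial PR; sampled at progression on osimertinib
246,female,65,ex,IVA (T4N1M1a),EGFR exon19 deletion;T790M,afatinib,1,PD,,initial PR; progression with T790M at sampling (day 555)
246,female,65,ex,IVA (T4N1M1a),EGFR exon19 deletion;T790M,osimertinib,2,PR,,no progression for over 700 days on osimertinib
263,female,79,never,IVB (T4N3M1c),EGFR exon19 deletion;T790M,afatinib,1,PD,,initial PR; progression before sampling
263,female,79,never,IVB (T4N3M1c),EGFR exon19 deletion;T790M,osimertinib,2,NE,,agent lazertinib; inconsistent dosing; death from COVID-19 ARDS
266,female,61,never,IVA (T2aN0M1a),EGFR exon19 deletion;exon20 Insertion,afatinib,1,PR,,sampled at diagnosis; PR on first-line afatinib
278,female,49,never,IVB (TXN3M1c),EGFR exon19 deletion;T790M,afatinib,1,PD,,initial PR; progression with T790M at sampling
278,female,49,never,IVB (TXN3M1c),EGFR exon19 deletion;T790M,osimertinib,2,PR,,agent lazertinib (third-generation class); PR after switch
282,female,83,never,IVB (TXN3M1c),EGFR exon19 insertion;T790M,afatinib,2,PD,,first-line gefitinib PR; PD on afatinib at sampling
282,female,83,never,IVB (TXN3M1c),EGFR exon19 insertion;T790M,osimertinib,3,PD,,agent lazertinib (third-generation class); PD at first evaluation
283,male,64,ex,IVB (T4N3M1c),EGFR exon21 L858R,afatinib,1,PD,,agent dacomitinib (second-generation class); initial PR; progression at sampling
305,male,97,never,IVB (T4N0M1c),EGFR exon21 L858R,afatinib,1,PR,,sampled at diagnosis; PR on first-line afatinib
316,male,70,ex,IVB (T1bN0M1c),EGFR exon19 deletion,afatinib,1,SD,-20,SD by RECIST 1.1 with tumor decrease; considered sensitive
331,female,85,never,IVA (T2bN2M1a),EGFR exon21 L858R,afatinib,1,SD,-10,SD by RECIST 1.1 with tumor decrease; considered sensitive
334,male,62,ex,IVA (T1bN0M1a),EGFR exon19 deletion,afatinib,1,PR,,sampled at diagnosis; PR on first-line afatinib
340,male,65,ex,IVB (T4N3M1c),EGFR exon19 deletion,afatinib,1,PR,,PR before voluntary discontinuation; progression after stop; pre-sampling PR used
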