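statement_id,theme,source,text,strongly_agree,agree,neutral,disagree,strongly_disagree,n_respondents
merit-01,patient_safety,B,Reduce medication errors,53,18,3,1,1,76
merit-02,patient_safety,B,Reduce adverse reactions,26,33,12,3,2,76
merit-03,patient_safety,B,Improve communication between healthcare providers,27,41,6,1,1,76
merit-04,patient_safety,B,Improve overall patient care experience,36,25,12,2,1,76
merit-05,cost,I,Improve prescriber's ability to prescribe more cost-effective medications,18,34,18,4,2,76
merit-06,cost,B,Increase prescriber's likelihood to discontinue unnecessary and/or ineffective medications,14,42,15,2,3,76
merit-07,cost,I,Decrease costs associated with adverse medication reactions and medication errors,51,16,6,2,1,76
merit-08,record_keeping,L,Improve storage of patient information and prescription records,53,21,2,0,0,76
merit-09,record_keeping,B,Improve prescriber's ability to trace patient's prescribing information,50,23,3,0,0,76
merit-10,record_keeping,L,Improve prescriber's ability to monitor medications and evaluate clinical outcomes,31,26,15,2,2,76
merit-11,workflow,B,Reduce wait times needed to call prescribers to clarify illegible or ambiguous medication orders,38,27,9,1,1,76
merit-12,workflow,L,Improve workflow of prescribers and other healthcare team by enabling copying and editing of prescribing information,14,22,17,12,11,76
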