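population_id,sex,karyomorph,count
Hongkouxiang,male,I,5
Hongkouxiang,female,III,1
Xuankouzhen,male,IV,1
Xuankouzhen,female,I,1
Xuankouzhen,female,IV,6
Qingcheng,male,I,2
Qingcheng,male,IV,1
Qingcheng,female,I,5
Qingcheng,female,IV,5
Wushanxiang,male,I,11
Wushanxiang,female,I,9
Wushanxiang,female,IV,1
Xilingzhen,male,I,5
Xilingzhen,male,IV,1
Xilingzhen,female,I,4
Xieyuanzhen-1,male,I,4
Xieyuanzhen-1,female,I,3
Hemingxiang-1,male,I,2
Hemingxiang-1,female,I,1
Hemingxiang-2,male,I,3
Hemingxiang-2,female,IV,7
Jinxingxiang-1,male,I,10
Jinxingxiang-1,male,IV,1
Jinxingxiang-1,female,I,2
Jinxingxiang-1,female,IV,3
Jinxingxiang-2,male,I,9
Jinxingxiang-2,male,IV,5
Jinxingxiang-2,female,I,21
Jinxingxiang-2,female,III,1
Jinxingxiang-2,female,IV,19
Jinxingxiang-3,male,I,7
Jinxingxiang-3,female,I,14
Gaotangsi,male,IV,8
Gaotangsi,female,I,1
Gaotangsi,female,IV,18
Xinchangzhen,male,I,4
Xinchangzhen,female,I,4
Datongxiang,male,I,9
Datongxiang,female,I,7
Shuikouzhen-2,male,I,3
Shuikouzhen-2,female,I,1
Nanbaoxiang-1,male,I,9
Nanbaoxiang-1,female,I,2
Huojingzhen,male,I,6
Huojingzhen,female,I,9
Gaohezhen-2,male,I,2
Gaohezhen-2,female,I,5
Daozuoxiang-1,male,I,4
Daozuoxiang-1,female,I,25
Daozuoxiang-2,male,I,4
Daozuoxiang-2,female,I,14
Pinglezhen,female,II,2
Tiantai-1,male,I,6
Tiantai-1,female,I,8
Tiantai-1,female,II,1
Tiantai-1,female,V,4
Tiantai-2,male,I,1
Tiantai-2,female,I,8
Bifeng,male,I,6
Bifeng,female,I,5
Huatouzhen,male,I,3
Huatouzhen,female,I,18
Emei,male,I,7
Emei,female,I,7
Shuangfuzhen,male,I,8
Shuangfuzhen,female,I,18
Luomuzhen,male,I,3
Luomuzhen,female,I,14
Xinglongzhen,male,I,2
Xinglongzhen,female,I,2
Kuankuoshui,male,I,7
Kuankuoshui,female,I,7
Leigongshan,male,I,2
Leigongshan,female,I,2
Xuefengshan,male,I,7
Xuefengshan,female,I,7
Hejiapingzhen,male,I,5
Hejiapingzhen,female,I,6
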