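date	time	subject	algorithm	beep	accuracy
03.09.2017	15:10	1	Backpropagation	10	0,5975
03.09.2017	17:44	1	Backpropagation	10	0,565
03.09.2017	18:11	1	Backpropagation	5	0,4675
03.09.2017	18:20	1	Backpropagation	5	0,56
03.09.2017	18:38	2	Backpropagation	10	0,5975
03.09.2017	18:48	2	Backpropagation	10	0,6
14.08.2018	10:06	4	Backpropagation	10	0,54
17.08.2018	13:03	5	Backpropagation	10	0,511
17.08.2018	13:28	6	Backpropagation	10	0,52
17.08.2018	13:56	7	Backpropagation	10	0,574
17.08.2018	20:13	8	Backpropagation	10	0,5419
19.08.2018	12:33	9	Backpropagation	10	0,5839
20.08.2018	18:15	10	Backpropagation	10	0,515
20.08.2018	18:45	11	Backpropagation	10	0,565
04.09.2017	22:32	1	Resilient backpropagation	10	0,5975
04.09.2017	22:40	1	Resilient backpropagation	10	0,5075
05.09.2017	22:09	2	Resilient backpropagation	10	0,5575
05.09.2017	22:17	2	Resilient backpropagation	10	0,52
04.09.2017	23:42	3	Resilient backpropagation	10	0,5575
14.08.2018	10:10	4	Resilient backpropagation	10	0,535
17.08.2018	13:15	5	Resilient backpropagation	10	0,524
17.08.2018	13:35	6	Resilient backpropagation	10	0,521
17.08.2018	14:01	7	Resilient backpropagation	10	0,56
17.08.2018	20:20	8	Resilient backpropagation	10	0,5575
19.08.2018	12:41	9	Resilient backpropagation	10	0,535
20.08.2018	18:20	10	Resilient backpropagation	10	0,525
20.08.2018	18:50	11	Resilient backpropagation	10	0,572
04.09.2017	22:52	1	Levenberg–Marquardt	10	0,6025
04.09.2017	23:04	1	Levenberg–Marquardt	10	0,66
05.09.2017	22:25	2	Levenberg–Marquardt	10	0,5675
05.09.2017	22:36	2	Levenberg–Marquardt	10	0,555
14.08.2018	10:03	4	Levenberg–Marquardt	10	0,544
17.08.2018	12:57	5	Levenberg–Marquardt	10	0,521
17.08.2018	13:20	6	Levenberg–Marquardt	10	0,56
17.08.2018	13:48	7	Levenberg–Marquardt	10	0,5875
17.08.2018	20:07	8	Levenberg–Marquardt	10	0,596
19.08.2018	12:23	9	Levenberg–Marquardt	10	0,55
20.08.2018	18:10	10	Levenberg–Marquardt	10	0,531
20.08.2018	18:37	11	Levenberg–Marquardt	10	0,601
20.08.2018	19:07	12	Levenberg–Marquardt	10	0,5503
05.09.2017	21:03	1	Error Correction	10	0,505
05.09.2017	21:32	1	Error Correction	10	0,4825
06.09.2017	22:00	2	Error Correction	10	0,4975
06.09.2017	22:05	2	Error Correction	10	0,4925
14.08.2018	10:15	4	Error Correction	10	0,505
17.08.2018	13:24	5	Error Correction	10	0,51
17.08.2018	13:40	6	Error Correction	10	0,4975
17.08.2018	14:14	7	Error Correction	10	0,505
17.08.2018	20:27	8	Error Correction	10	0,5495
19.08.2018	12:50	9	Error Correction	10	0,521
20.08.2018	18:26	10	Error Correction	10	0,4984
20.08.2018	18:00	11	Error Correction	10	0,521
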